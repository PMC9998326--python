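"""Feature extraction: spatiotemporal PCA and ICA mean/variance features.

Two backends feed the classifier:

* **Spatiotemporal PCA** — the channels x window samples of each trial are
  concatenated (channel-major) into one vector; the training-set covariance
  is eigendecomposed and trials are projected onto the M leading
  eigenvectors. The projections are the features (M per trial).

* **ICA mean/variance** — the window data are compressed to M dimensions by
  PCA whitening; the average training epoch is subtracted from every trial
  (evoked subtraction, which removes bias from activity phase-locked to the
  stimulus); fixed-point ICA with symmetric orthogonalization and the tanh
  contrast estimates M independent components. Per trial and component the
  features are (a) the mean of the demixed component over the window and
  (b) the variance of the component after subtracting that component's
  training-average time course — computed as the mean of squares, i.e. the
  mean of the template-subtracted component is taken to be zero. Feature
  order is [means(1..M), variances(1..M)], 2M features in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from premove.containers import EpochSet
from premove.preprocessing import _fit_fastica

__all__ = [
    "WindowSpec",
    "PCABasis",
    "FeatureICAModel",
    "FeatureMatrix",
    "fit_spatiotemporal_pca",
    "st_features",
    "fit_feature_ica",
    "ica_features",
    "effective_n_components",
]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window in ms relative to stimulus onset."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("start_ms must precede end_ms")

    @property
    def size_ms(self) -> float:
        return self.end_ms - self.start_ms


def effective_n_components(requested: int, n_channels: int) -> int:
    """Component count actually used: ``min(requested, n_channels)``, >= 1.

    The fit additionally clips to the empirical data rank, so
    rank-deficient inputs (e.g. average-referenced data, whose rank is
    channels - 1) automatically lose one further component.
    """
    return max(1, min(requested, n_channels))


@dataclass
class PCABasis:
    """Spatiotemporal PCA basis fitted on training trials."""

    eigenvectors: np.ndarray  # (channels*window_samples, M), orthonormal columns
    eigenvalues: np.ndarray  # (M,), non-increasing
    mean: np.ndarray  # training mean vector
    window: WindowSpec
    channel_names: list[str]
    fs: float

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class FeatureICAModel:
    """Fitted ICA feature extractor (compression, demixing, templates)."""

    channel_mean: np.ndarray  # (channels,)
    compression: np.ndarray  # (M, channels), PCA whitening
    decompression: np.ndarray  # (channels, M)
    unmixing: np.ndarray  # W (M, M), compressed space
    mixing: np.ndarray  # A = W^-1
    evoked_template: np.ndarray  # (M, window_samples), compressed average epoch
    component_templates: np.ndarray  # (M, window_samples), demixed average
    window: WindowSpec
    channel_names: list[str]
    fs: float

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def channel_patterns(self) -> np.ndarray:
        """Channel-space topography of each component (columns)."""
        return self.decompression @ self.mixing


@dataclass
class FeatureMatrix:
    """Trials x features with per-column provenance."""

    values: np.ndarray
    descriptors: list[tuple]
    backend: str

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _window_vectors(epochs: EpochSet, window: WindowSpec) -> np.ndarray:
    """Channel-major concatenation of the window data, one row per trial."""
    x = epochs.window_data(window.start_ms, window.end_ms)  # (n, C, T)
    n = x.shape[0]
    return x.reshape(n, -1)  # row-major: all samples of channel 1, then 2, ...


def fit_spatiotemporal_pca(train_epochs: EpochSet, window: WindowSpec, m: int) -> PCABasis:
    """Eigendecomposition of the training covariance of spatiotemporal vectors.

    ``m`` is clipped to the covariance rank with a warning when too large.
    """
    x = _window_vectors(train_epochs, window)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    rank = max(int(np.sum(evals > 1e-12 * max(evals[0], 1e-300))), 1)
    if m > rank:
        warnings.warn(f"M={m} exceeds data rank {rank}; clipped")
        m = rank
    return PCABasis(
        eigenvectors=evecs[:, :m],
        eigenvalues=evals[:m],
        mean=mean,
        window=window,
        channel_names=list(train_epochs.channel_names),
        fs=train_epochs.fs,
    )


def st_features(epochs: EpochSet, basis: PCABasis) -> FeatureMatrix:
    """Project trials onto the PCA basis (training mean removed)."""
    _check_compat(epochs, basis.channel_names, basis.fs)
    x = _window_vectors(epochs, basis.window)
    if x.shape[1] != basis.eigenvectors.shape[0]:
        raise ValueError("window sample count does not match the fitted basis")
    vals = (x - basis.mean) @ basis.eigenvectors
    return FeatureMatrix(
        values=vals,
        descriptors=[("pc", k) for k in range(basis.n_components)],
        backend="st_pca",
    )


def fit_feature_ica(
    train_epochs: EpochSet,
    window: WindowSpec,
    m: int = 30,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    max_restarts: int = 1,
    strict: bool = False,
) -> FeatureICAModel:
    """Fit the ICA feature extractor on training trials.

    Steps: the average training epoch is subtracted from each trial (evoked
    subtraction, so activity phase-locked to the stimulus cannot bias the
    decomposition), the residuals are PCA-whitened to ``m`` dimensions
    (``m`` reduced to the channel count and to the data rank when fewer
    dimensions are available), and fixed-point ICA (symmetric, tanh contrast) runs on
    the compressed residuals. Because every operator is linear, compression
    and evoked subtraction commute in the transform chain; estimating the
    compression from the residuals makes the extractor exactly invariant to
    any waveform added to every training trial. Deterministic under
    ``seed``.
    """
    x = train_epochs.window_data(window.start_ms, window.end_ms)  # (n, C, T)
    n, c, t = x.shape
    m_eff = effective_n_components(m, c)

    evoked_ch = x.mean(axis=0)  # (C, T) average epoch
    resid_ch = x - evoked_ch[None]
    flat = resid_ch.transpose(1, 0, 2).reshape(c, n * t)  # zero mean by construction
    cov = (flat @ flat.T) / flat.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = max(int(np.sum(evals > 1e-12 * max(evals[0], 1e-300))), 1)
    if m_eff > rank:
        warnings.warn(f"M={m_eff} exceeds compressed-data rank {rank}; clipped")
        m_eff = rank
    comp = evecs[:, :m_eff].T / np.sqrt(evals[:m_eff])[:, None]
    decomp = evecs[:, :m_eff] * np.sqrt(evals[:m_eff])[None, :]

    evoked = comp @ evoked_ch  # (M, T) compressed average epoch
    resid = np.einsum("mc,nct->nmt", comp, resid_ch)
    mean = np.zeros(c)

    w = _fit_fastica(
        resid.transpose(1, 0, 2).reshape(m_eff, n * t).T,
        m_eff,
        "logcosh",
        seed,
        tol,
        max_iter,
        max_restarts,
        strict,
    )
    a = np.linalg.pinv(w)
    return FeatureICAModel(
        channel_mean=mean,
        compression=comp,
        decompression=decomp,
        unmixing=w,
        mixing=a,
        evoked_template=evoked,
        component_templates=w @ evoked,
        window=window,
        channel_names=list(train_epochs.channel_names),
        fs=train_epochs.fs,
    )


def ica_features(epochs: EpochSet, model: FeatureICAModel) -> FeatureMatrix:
    """Mean and template-subtracted variance of each demixed component.

    The variance uses 1/N normalization (mean of squares of the
    template-subtracted component, no per-trial recentering).
    """
    _check_compat(epochs, model.channel_names, model.fs)
    w = model.window
    x = epochs.window_data(w.start_ms, w.end_ms)
    if x.shape[2] != model.evoked_template.shape[1]:
        raise ValueError("window sample count does not match the fitted model")
    y = np.einsum("mc,nct->nmt", model.compression, x - model.channel_mean[None, :, None])
    s = np.einsum("rm,nmt->nrt", model.unmixing, y)  # (n, M, T)
    means = s.mean(axis=2)
    resid = s - model.component_templates[None]
    variances = np.mean(resid**2, axis=2)
    m = model.n_components
    return FeatureMatrix(
        values=np.hstack([means, variances]),
        descriptors=[("ic", k, "mean") for k in range(m)]
        + [("ic", k, "variance") for k in range(m)],
        backend="ica",
    )


def _check_compat(epochs: EpochSet, channel_names: list[str], fs: float) -> None:
    if list(epochs.channel_names) != list(channel_names):
        raise ValueError("epoch channel set does not match the fitted model")
    if epochs.fs != fs:
        raise ValueError(f"epoch rate {epochs.fs} Hz does not match model rate {fs} Hz")
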