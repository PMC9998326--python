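"""Neurophysiological read-outs of a fitted decoder.

* :func:`classifier_topography` — the channel-space pattern ν of the signal
  whose window-mean is most predictive of right- vs. left-hand choice,
  obtained by mapping the classifier weights on the component-mean features
  (standardization undone) through the ICA mixing and PCA decompression
  operators. Sign convention: the left-hemisphere channel of maximum
  magnitude is positive, so positive values are evidence for an upcoming
  right-hand movement.
* :func:`tf_difference` — Morlet time–frequency power per class, combined
  as the normalized difference (right − left) / (right + left); values lie
  in [−1, 1] and vanish where class powers are equal.
* :func:`minimum_norm` — minimum-norm estimation with free-oriented
  dipoles: source coefficients ``G^T (G G^T + reg I)^{-1} ν`` with per-source
  amplitude the Euclidean norm over the three orientations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from premove.classification import ClassifierModel
from premove.containers import EpochSet
from premove.features import FeatureICAModel
from premove.synthetic_data import Leadfield

__all__ = [
    "Topography",
    "TFMap",
    "SourceEstimate",
    "classifier_topography",
    "tf_difference",
    "minimum_norm",
    "hemisphere_of",
    "LEFT_HEMISPHERE_TF",
    "RIGHT_HEMISPHERE_TF",
    "LEFT_HEMISPHERE_TF_SHORT",
    "RIGHT_HEMISPHERE_TF_SHORT",
]

#: Default per-hemisphere channel sets for the time–frequency contrast
#: (sensorimotor neighborhoods around C1/C2).
LEFT_HEMISPHERE_TF = ["C1", "C3", "CCP1h", "FC1", "FCC1h", "FCC3h"]
RIGHT_HEMISPHERE_TF = ["C2", "C4", "CCP2h", "FC2", "FCC2h", "FCC4h"]
#: Shorter 4-channel variants.
LEFT_HEMISPHERE_TF_SHORT = ["FCC1h", "C1", "CCP1h", "FCC3h"]
RIGHT_HEMISPHERE_TF_SHORT = ["FCC2h", "C2", "CCP2h", "FCC4h"]

_LABEL_RE = re.compile(r"^[A-Za-z]+?(\d+)h?$")


def hemisphere_of(label: str) -> str:
    """``"left"``, ``"right"`` or ``"midline"`` from a 10-5 label.

    Odd electrode numbers are over the left hemisphere, even over the right,
    ``z`` labels on the midline.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        return "midline"
    return "left" if int(m.group(1)) % 2 == 1 else "right"


@dataclass
class Topography:
    """Per-channel pattern; positive = evidence for a right-hand choice."""

    values: np.ndarray
    channel_names: list[str]

    def correlation(self, other: np.ndarray) -> float:
        return float(np.corrcoef(self.values, np.asarray(other))[0, 1])


def classifier_topography(
    feature_model: FeatureICAModel,
    classifier: ClassifierModel,
    epochs: EpochSet | None = None,
    mode: str = "mixing",
) -> Topography:
    """Channel pattern of the most classification-relevant window-mean signal.

    ``mode="mixing"`` (default) forward-projects the mean-feature weight
    vector through the ICA mixing and PCA decompression operators.
    ``mode="covariance"`` instead multiplies the channel-space discriminant
    filter by the covariance of the window-averaged channel data (requires
    ``epochs``); both give the activation pattern of the discriminant, up to
    scale, under their respective noise models.
    """
    m = feature_model.n_components
    if classifier.feature_backend not in ("ica", "unknown"):
        raise ValueError("classifier was not trained on ICA features")
    if len(classifier.weights) != 2 * m:
        raise ValueError(
            f"classifier has {len(classifier.weights)} weights; expected {2 * m} "
            "(mean + variance features of this model)"
        )
    w_mean = classifier.weights[:m] / classifier.scaler_scale[:m]
    if mode == "mixing":
        nu = feature_model.decompression @ (feature_model.mixing @ w_mean)
    elif mode == "covariance":
        if epochs is None:
            raise ValueError("mode='covariance' requires epochs")
        filt = feature_model.compression.T @ (feature_model.unmixing.T @ w_mean)
        xw = epochs.window_data(feature_model.window.start_ms, feature_model.window.end_ms)
        xbar = xw.mean(axis=2)  # (trials, channels)
        cov = np.cov(xbar, rowvar=False)
        nu = cov @ filt
    else:
        raise ValueError("mode must be 'mixing' or 'covariance'")

    names = feature_model.channel_names
    left = [i for i, ch in enumerate(names) if hemisphere_of(ch) == "left"]
    if left:
        peak = left[int(np.argmax(np.abs(nu[left])))]
        if nu[peak] < 0:
            nu = -nu
    return Topography(values=nu, channel_names=list(names))


@dataclass
class TFMap:
    """Normalized right-vs-left power difference over frequencies x times."""

    values: np.ndarray  # (n_freqs, n_times), in [-1, 1] (nan where masked)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # ms
    channels: list[str]

    def band_mean(self, f_lo: float, f_hi: float) -> float:
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return float(np.nanmean(self.values[sel]))


def _morlet_power(
    epochs: EpochSet, channels: list[str], freqs: np.ndarray, cycles: float
) -> np.ndarray:
    """Trial- and channel-averaged Morlet wavelet power, (n_freqs, n_times).

    Edge samples with incomplete wavelet support are masked with NaN.
    """
    from mne.time_frequency import tfr_array_morlet

    sub = epochs.select_channels(channels)
    # the wavelet at frequency f spans ~±5 sigma_t = ±5 * cycles / (2 pi f);
    # frequencies whose wavelet exceeds the epoch are masked entirely
    half_widths_s = 5.0 * cycles / (2.0 * np.pi * freqs)
    n_times = epochs.n_times
    usable = 2 * half_widths_s * epochs.fs + 1 <= n_times
    avg = np.full((len(freqs), n_times), np.nan)
    if usable.any():
        power = tfr_array_morlet(
            sub.data,
            sfreq=epochs.fs,
            freqs=freqs[usable],
            n_cycles=cycles,
            output="power",
            zero_mean=True,
        )
        avg[usable] = power.mean(axis=(0, 1))
    t0, t1 = epochs.times[0], epochs.times[-1]
    for i, hw in enumerate(half_widths_s * 1000.0):
        avg[i, (epochs.times - t0 < hw) | (t1 - epochs.times < hw)] = np.nan
    return avg


def tf_difference(
    epochs_right: EpochSet,
    epochs_left: EpochSet,
    channels: list[str],
    f_lo: float = 2.0,
    f_hi: float = 40.0,
    t_window: tuple[float, float] = (-150.0, 150.0),
    cycles: float = 7.0,
    f_step: float = 1.0,
) -> TFMap:
    """Normalized class power difference (right − left) / (right + left).

    Power is Morlet-wavelet power averaged over trials and over the listed
    channels, per class; the map is restricted to ``t_window``.
    """
    if list(epochs_right.channel_names) != list(epochs_left.channel_names):
        raise ValueError("epoch sets must share the channel set")
    if epochs_right.fs != epochs_left.fs:
        raise ValueError("epoch sets must share the sampling rate")
    if f_hi >= epochs_right.fs / 2:
        raise ValueError(f"f_hi {f_hi} Hz is at or above Nyquist")
    freqs = np.arange(f_lo, f_hi + f_step / 2, f_step)
    x1 = _morlet_power(epochs_right, channels, freqs, cycles)
    x2 = _morlet_power(epochs_left, channels, freqs, cycles)
    denom = x1 + x2
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.where(denom > 0, (x1 - x2) / denom, 0.0)
    diff[np.isnan(denom)] = np.nan
    tmask = (epochs_right.times >= t_window[0]) & (epochs_right.times <= t_window[1])
    return TFMap(
        values=diff[:, tmask],
        freqs=freqs,
        times=epochs_right.times[tmask],
        channels=list(channels),
    )


@dataclass
class SourceEstimate:
    """Per-source amplitude (norm over 3 free orientations)."""

    amplitudes: np.ndarray  # (n_sources,), >= 0
    coefficients: np.ndarray  # (n_sources, 3)
    source_positions: np.ndarray

    @property
    def peak_source(self) -> int:
        return int(np.argmax(self.amplitudes))


def minimum_norm(
    topography: Topography | np.ndarray,
    leadfield: Leadfield,
    reg: float = 1e-16,
) -> SourceEstimate:
    """Regularized minimum-norm inverse with free-oriented dipoles.

    Source coefficients are ``G^T (G G^T + reg I)^{-1} ν`` where ``G`` is the
    channels x (3 * n_sources) gain; the per-source amplitude is the
    Euclidean norm of its three orientation coefficients.
    """
    if isinstance(topography, Topography):
        if list(topography.channel_names) != list(leadfield.channel_names):
            raise ValueError("topography channels do not match the leadfield")
        nu = topography.values
    else:
        nu = np.asarray(topography, dtype=float)
    n_ch, n_src, _ = leadfield.gain.shape
    if len(nu) != n_ch:
        raise ValueError("topography length does not match the leadfield")
    if reg < 0:
        raise ValueError("reg must be >= 0")
    g = leadfield.gain.reshape(n_ch, n_src * 3)
    gram = g @ g.T + reg * np.eye(n_ch)
    if reg == 0 and np.linalg.matrix_rank(gram) < n_ch:
        raise np.linalg.LinAlgError("singular gram matrix; use reg > 0")
    coeffs = (g.T @ np.linalg.solve(gram, nu)).reshape(n_src, 3)
    return SourceEstimate(
        amplitudes=np.linalg.norm(coeffs, axis=1),
        coefficients=coeffs,
        source_positions=leadfield.source_positions,
    )
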