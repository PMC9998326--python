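"""Continuous-to-epoched preprocessing with strictly pre-stimulus cleaning.

The chain mirrors standard single-trial decoding practice: zero-phase FIR
filtering, stimulus-locked epoching, polyphase resampling, automated
variance-based channel/trial rejection, re-referencing, baseline correction,
and an artifact-reduction ICA. Every data-dependent cleaning decision
(rejection scores, ICA fit) uses only samples before stimulus onset, so no
information from the task-execution period can leak into the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from premove.containers import EpochSet, Recording

__all__ = [
    "fir_filter",
    "extract_epochs",
    "resample_epochs",
    "reject_outliers",
    "rereference",
    "baseline_correct",
    "clean_ica",
    "detect_movement_onset",
    "CleaningICAModel",
    "RejectionReport",
]

#: Sentinel returned by :func:`detect_movement_onset` when no movement found.
NO_MOVEMENT = float("nan")


def _design_fir(kind: str, cutoff: float, order: int, fs: float) -> np.ndarray:
    if kind not in ("highpass", "lowpass"):
        raise ValueError("kind must be 'highpass' or 'lowpass'")
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({fs / 2} Hz)")
    if order < 2:
        raise ValueError("order must be >= 2")
    numtaps = order + 1
    if numtaps % 2 == 0:  # type-I (odd-length) kernel: integer group delay,
        numtaps += 1  # no forced zero at Nyquist for the high-pass
    low = signal.firwin(numtaps, cutoff, fs=fs, pass_zero=True)
    if kind == "lowpass":
        return low
    # high-pass as delta - lowpass: DC gain is exactly zero even for kernels
    # short relative to 1/cutoff
    taps = -low
    taps[(numtaps - 1) // 2] += 1.0
    return taps


def _filter_array(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase filtering: linear-phase kernel + group-delay compensation.

    The signal is zero-padded at both ends; roughly ``len(taps)/2`` samples
    at each edge carry filter transients.
    """
    delay = (len(taps) - 1) // 2
    y = signal.fftconvolve(x, taps[np.newaxis, :], mode="full", axes=-1)
    return y[..., delay : delay + x.shape[-1]]


def fir_filter(obj: Recording | EpochSet, kind: str, cutoff: float, order: int):
    """Zero-phase FIR high- or low-pass filter, length preserving.

    Works on a continuous :class:`Recording` (filtering EEG, not EMG) or on
    an :class:`EpochSet` (filtering along the time axis of every trial).
    """
    taps = _design_fir(kind, cutoff, order, obj.fs)
    out = obj.copy()
    if isinstance(obj, Recording):
        out.data = _filter_array(out.data, taps)
    else:
        n, c, t = out.data.shape
        out.data = _filter_array(out.data.reshape(n * c, t), taps).reshape(n, c, t)
    return out


def extract_epochs(recording: Recording, pre_s: float = 2.5, post_s: float = 2.5) -> EpochSet:
    """Cut stimulus-locked epochs (t = 0 at the stimulus sample).

    Events too close to the record edge are dropped with a warning.
    """
    fs = recording.fs
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    times = np.arange(-n_pre, n_post + 1) / fs * 1000.0
    trials, labels, dropped = [], [], []
    for k, (t0, lab) in enumerate(zip(recording.events, recording.labels)):
        i = int(round(t0 * fs))
        if i - n_pre < 0 or i + n_post >= recording.n_samples:
            dropped.append(k)
            continue
        trials.append(recording.data[:, i - n_pre : i + n_post + 1])
        labels.append(lab)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} event(s) too close to the record edge: {dropped}")
    if not trials:
        raise ValueError("no events with full pre/post context available")
    return EpochSet(
        data=np.stack(trials),
        times=times,
        fs=fs,
        channel_names=list(recording.channel_names),
        labels=np.array(labels),
    )


def resample_epochs(epochs: EpochSet, target_fs: float = 1000.0) -> EpochSet:
    """Anti-aliased polyphase resampling; t = 0 is preserved.

    Non-integer rate ratios are handled by rational resampling.
    """
    if target_fs > epochs.fs:
        raise ValueError("target_fs must not exceed the current rate")
    if target_fs == epochs.fs:
        return epochs.copy()
    from fractions import Fraction

    frac = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=2)
    times = epochs.times[0] + np.arange(data.shape[2]) / target_fs * 1000.0
    return replace(
        epochs,
        data=data,
        times=times,
        fs=target_fs,
        labels=epochs.labels.copy(),
        channel_names=list(epochs.channel_names),
    )


@dataclass
class RejectionReport:
    removed_channels: list[str]
    removed_trials: list[int]
    channel_scores: dict[str, float]
    trial_scores: np.ndarray
    excluded_channels: list[str]


def reject_outliers(
    epochs: EpochSet,
    z_thresh: float = 3.5,
    exclude_channels: list[str] | tuple[str, ...] = (),
) -> tuple[EpochSet, RejectionReport]:
    """Automated variance-based channel and trial rejection.

    Robust z-scores (median/MAD) of per-channel and per-trial log-variance
    are computed on the **pre-stimulus segment only**; entries above
    ``z_thresh`` are removed. Channels in ``exclude_channels`` (e.g.
    peripheral electrodes affected by the reaching movement) are removed
    unconditionally.
    """
    if epochs.n_channels < 3 or epochs.n_trials < 3:
        raise ValueError("need at least 3 channels and 3 trials")
    pre = epochs.data[:, :, epochs.pre_mask]
    var = pre.var(axis=2)  # (trials, channels)

    excluded = [ch for ch in exclude_channels if ch in epochs.channel_names]
    keep_ch = np.array([ch not in excluded for ch in epochs.channel_names])

    ch_log = np.log(var.mean(axis=0) + 1e-30)
    ch_z = _robust_z(ch_log[keep_ch])
    bad = np.flatnonzero(keep_ch)[ch_z > z_thresh]
    keep_ch[bad] = False
    if not keep_ch.any():
        raise ValueError("data quality: all channels flagged")
    removed_channels = [ch for ch, k in zip(epochs.channel_names, keep_ch) if not k and ch not in excluded]

    tr_log = np.log(var[:, keep_ch].mean(axis=1) + 1e-30)
    tr_z = _robust_z(tr_log)
    keep_tr = tr_z <= z_thresh
    if not keep_tr.any():
        raise ValueError("data quality: all trials flagged")
    removed_trials = list(np.flatnonzero(~keep_tr))

    out = EpochSet(
        data=epochs.data[np.ix_(keep_tr, keep_ch)].copy(),
        times=epochs.times.copy(),
        fs=epochs.fs,
        channel_names=[ch for ch, k in zip(epochs.channel_names, keep_ch) if k],
        labels=epochs.labels[keep_tr].copy(),
        reference=epochs.reference,
    )
    report = RejectionReport(
        removed_channels=removed_channels,
        removed_trials=removed_trials,
        channel_scores=dict(zip(epochs.channel_names, ch_log)),
        trial_scores=tr_z,
        excluded_channels=excluded,
    )
    return out, report


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad if mad > 0 else (x.std() or 1.0)
    return (x - med) / scale


def rereference(epochs: EpochSet, mode: str = "average") -> EpochSet:
    """Re-reference to the channel average or to a named channel.

    Channel mode subtracts the named channel and removes it from the data.
    """
    out = epochs.copy()
    if mode == "average":
        out.data = out.data - out.data.mean(axis=1, keepdims=True)
        out.reference = "average"
        return out
    if mode not in epochs.channel_names:
        raise ValueError(f"reference channel {mode!r} not present")
    ref = epochs.channel_names.index(mode)
    keep = [i for i in range(epochs.n_channels) if i != ref]
    out.data = epochs.data[:, keep, :] - epochs.data[:, ref : ref + 1, :]
    out.channel_names = [epochs.channel_names[i] for i in keep]
    out.reference = mode
    return out


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of the full pre-stimulus segment per channel/trial."""
    out = epochs.copy()
    base = out.data[:, :, out.pre_mask].mean(axis=2, keepdims=True)
    out.data = out.data - base
    return out


@dataclass
class CleaningICAModel:
    """Fitted artifact-reduction ICA (compression + demixing/mixing)."""

    mean: np.ndarray  # (channels,)
    compression: np.ndarray  # (M, channels), whitening included
    decompression: np.ndarray  # (channels, M)
    unmixing: np.ndarray  # W, (M, M) in compressed space
    mixing: np.ndarray  # A = W^-1
    removed_components: list[int]
    component_kurtosis: np.ndarray

    @property
    def channel_patterns(self) -> np.ndarray:
        """Channel-space topography of each component (columns)."""
        return self.decompression @ self.mixing

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Apply compression + component removal to (..., channels, time)."""
        x = data - self.mean[:, None]
        y = np.einsum("mc,...ct->...mt", self.compression, x)
        if self.removed_components:
            rm = self.removed_components
            s = np.einsum("rm,...mt->...rt", self.unmixing[rm], y)
            y = y - np.einsum("mr,...rt->...mt", self.mixing[:, rm], s)
        return np.einsum("cm,...mt->...ct", self.decompression, y) + self.mean[:, None]

    def sources(self, data: np.ndarray) -> np.ndarray:
        x = data - self.mean[:, None]
        y = np.einsum("mc,...ct->...mt", self.compression, x)
        return np.einsum("rm,...mt->...rt", self.unmixing, y)


def _fit_fastica(
    data: np.ndarray,
    n_components: int,
    fun: str,
    seed: int,
    tol: float,
    max_iter: int,
    max_restarts: int,
    strict: bool = False,
) -> np.ndarray:
    """Symmetric fixed-point ICA on pre-whitened (samples, dims) data.

    Restarts with a fresh seed on non-convergence. The symmetric convergence
    criterion requires *every* component to stabilize, which near-Gaussian
    subspaces (rotation-indeterminate by construction) rarely satisfy even
    though the identifiable non-Gaussian components converge early; after
    the restarts are exhausted the last estimate is therefore returned with
    a warning, unless ``strict=True``, which raises instead.
    """
    last_w, last_err = None, None
    for attempt in range(max_restarts + 1):
        ica = FastICA(
            n_components=n_components,
            algorithm="parallel",
            whiten=False,
            fun=fun,
            tol=tol,
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ica.fit(data)
        conv_fail = [w for w in caught if "did not converge" in str(w.message).lower()]
        if not conv_fail:
            return ica.components_
        last_w, last_err = ica.components_, str(conv_fail[0].message)
    msg = (
        f"FastICA did not fully converge after {max_restarts + 1} attempts "
        f"(n_components={n_components}, tol={tol}, max_iter={max_iter}): {last_err}"
    )
    if strict:
        raise RuntimeError(msg)
    warnings.warn(msg + "; keeping the final estimate")
    return last_w


def clean_ica(
    epochs: EpochSet,
    n_components: int = 50,
    remove="auto_ocular",
    kurtosis_thresh: float = 3.0,
    anterior_pair: tuple[str, str] = ("AFp1", "AFp2"),
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    max_restarts: int = 1,
    strict: bool = False,
    fit_decim: int = 1,
) -> tuple[EpochSet, CleaningICAModel]:
    """Artifact-reduction ICA fitted on pre-stimulus data only.

    Fixed-point ICA with symmetric orthogonalization and a Gaussian contrast
    function on data compressed to ``n_components`` dimensions (reduced to
    ``channels - 1`` when fewer channels are available). The fitted transform
    and component removal are applied to the full epoch.

    ``remove`` is either a list of component indices or ``"auto_ocular"``:
    flag components whose channel pattern loads maximally on the most
    anterior channel pair (``anterior_pair`` when present, else the first
    frontopolar labels found) and whose time course has excess kurtosis above
    ``kurtosis_thresh``. ``fit_decim`` subsamples the pre-stimulus samples
    used for fitting (the transform is always applied at full resolution).
    """
    n, c, _ = epochs.data.shape
    # with fewer channels than requested components, fall back to channels - 1
    m = n_components if c >= n_components else max(c - 1, 1)

    pre = epochs.data[:, :, epochs.pre_mask]
    x = pre.transpose(1, 0, 2).reshape(c, -1)[:, ::fit_decim]
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    cov = (xc @ xc.T) / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > 1e-12 * evals[0]))
    m = min(m, rank)
    comp = evecs[:, :m].T / np.sqrt(evals[:m])[:, None]  # whitening (M, C)
    decomp = evecs[:, :m] * np.sqrt(evals[:m])[None, :]  # (C, M)

    y = comp @ xc  # (M, samples), unit variance
    w = _fit_fastica(y.T, m, "exp", seed, tol, max_iter, max_restarts, strict)
    a = np.linalg.pinv(w)

    from scipy.stats import kurtosis

    sources = w @ y
    kurt = kurtosis(sources, axis=1)

    if isinstance(remove, str) and remove == "auto_ocular":
        patterns = decomp @ a
        anterior = [ch for ch in anterior_pair if ch in epochs.channel_names]
        if not anterior:
            anterior = [ch for ch in epochs.channel_names if ch.startswith(("AFp", "Fp"))][:2]
        ant_idx = {epochs.channel_names.index(ch) for ch in anterior}
        removed = [
            k
            for k in range(m)
            if int(np.argmax(np.abs(patterns[:, k]))) in ant_idx and kurt[k] > kurtosis_thresh
        ]
    else:
        removed = sorted(int(k) for k in remove)

    model = CleaningICAModel(
        mean=mean,
        compression=comp,
        decompression=decomp,
        unmixing=w,
        mixing=a,
        removed_components=removed,
        component_kurtosis=kurt,
    )
    out = epochs.copy()
    out.data = model.transform(epochs.data)
    return out, model


def detect_movement_onset(
    emg: np.ndarray,
    fs: float,
    stim_offset_s: float = 0.0,
    hp_hz: float = 20.0,
    lp_hz: float = 10.0,
    flat_rms: float = 1e-9,
) -> float:
    """Movement onset (ms after the stimulus) from a single-trial EMG segment.

    The envelope is the rectified 20 Hz high-passed EMG smoothed by a 10 Hz
    low-pass; onset is the first post-stimulus sample where the envelope
    exceeds 50% of its post-stimulus maximum. ``emg`` must cover the
    stimulus (at ``stim_offset_s`` into the segment) to the end of the trial.
    Returns ``nan`` when the EMG is flat (no movement).
    """
    emg = np.asarray(emg, dtype=float)
    if emg.ndim != 1:
        raise ValueError("emg must be a 1-D single-channel segment")
    hp = _design_fir("highpass", hp_hz, max(int(0.2 * fs), 10), fs)
    lp = _design_fir("lowpass", lp_hz, max(int(0.2 * fs), 10), fs)
    env = _filter_array(np.abs(_filter_array(emg[None, :], hp)), lp)[0]
    start = int(round(stim_offset_s * fs))
    post = env[start:]
    peak = post.max(initial=0.0)
    if peak <= flat_rms or np.sqrt(np.mean(emg**2)) <= flat_rms:
        return NO_MOVEMENT
    onset = int(np.argmax(post > 0.5 * peak))
    return onset / fs * 1000.0
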