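"""Synthetic EEG/EMG sessions with known ground truth.

The generator emulates the statistical structure of a cued reaching session
with free hand choice: ~1000 trials separated by a jittered 2.5–3.5 s
inter-stimulus interval, sequentially biased (two-state Markov) hand choices,
and two classes of predictive signal around stimulus onset:

* a lateralized modulation of 10–25 Hz band power (event-related
  desynchronization contralateral to the upcoming hand, synchronization
  ipsilaterally), injected as a multiplicative amplitude modulation of two
  hemisphere-specific band-limited noise sources, and
* a slow potential shift with hand-dependent sign through the same smooth
  spatial topographies (centered near C1/C2).

Background activity is 1/f-shaped Gaussian noise plus an ongoing ~10 Hz
oscillation. Ocular (blink) artifacts are mixed in through a frontal
topography, and bipolar EMG channels carry a burst starting at movement
onset (lognormal latency, median ≈ 300 ms after the stimulus).

Everything is deterministic given ``SyntheticConfig.seed``, and all injected
structure is returned as :class:`GroundTruth` so downstream stages can be
tested without real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from premove.containers import Recording

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Leadfield",
    "generate_labels",
    "generate_session",
    "make_leadfield",
    "DEFAULT_CHANNELS",
    "channel_positions",
]

#: Default montage for generated sessions: a sensorimotor-centered 10-5 set
#: plus the CPz reference, the frontopolar pair used for ocular-artifact
#: checks (AFp1/AFp2), and a few surrounding channels.
DEFAULT_CHANNELS = [
    "AFp1", "AFp2", "F3", "Fz", "F4",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "FCC5h", "FCC3h", "FCC1h", "FCC2h", "FCC4h", "FCC6h",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CCP5h", "CCP3h", "CCP1h", "CCP2h", "CCP4h", "CCP6h",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P3", "Pz", "P4", "POz",
]

_EMG_NAMES = ["EMGleft", "EMGright"]


def channel_positions(channel_names: list[str]) -> np.ndarray:
    """3-D head-surface positions (meters) for 10-5 channel labels.

    Positions come from the standard 10-5 montage; x grows to the right,
    y to the front, z up. Unknown labels raise ``KeyError``.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channel_names if ch not in pos]
    if missing:
        raise KeyError(f"labels not in the 10-5 montage: {missing}")
    return np.array([pos[ch] for ch in channel_names])


@dataclass
class SyntheticConfig:
    """Parameters of a generated session.

    Attributes
    ----------
    effect_snr : float
        Dimensionless strength of the predictive modulation relative to
        background; 0 yields null data (labels carry no EEG information).
        It scales both the ERD/ERS modulation depth and the slow shift.
    effect_window : (float, float)
        Interval in ms relative to stimulus onset in which the predictive
        modulation is active.
    slow_shift_uV : float
        Amplitude of the hand-dependent slow potential shift at
        ``effect_snr = 1`` (microvolts at the topography peak).
    movement_latency : (float, float)
        Median (ms) and log-normal sigma (dimensionless) of the
        stimulus-to-movement-onset latency.
    dwell_s : float
        Post-trial dwell (reach + return to home position) added to the
        jittered inter-stimulus interval, so successive stimulus gaps are
        ``dwell_s + U(iti_range)``.
    """

    n_channels: int = len(DEFAULT_CHANNELS)
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    fs: float = 1000.0
    n_trials: int = 1080
    iti_range: tuple[float, float] = (2.5, 3.5)
    effect_snr: float = 1.0
    effect_window: tuple[float, float] = (-150.0, 150.0)
    erd_band: tuple[float, float] = (10.0, 25.0)
    slow_shift_uV: float = 5.0
    p_right: float = 0.5
    p_stay: float = 0.7
    movement_latency: tuple[float, float] = (300.0, 0.35)
    artifact_rate: float = 6.0
    dwell_s: float = 1.2
    background_rms_uV: float = 10.0
    alpha_rms_uV: float = 4.0
    carrier_rms_uV: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_names = list(self.channel_names)
        self.n_channels = len(self.channel_names)
        if self.effect_snr < 0:
            raise ValueError("effect_snr must be >= 0")
        for p, name in ((self.p_right, "p_right"), (self.p_stay, "p_stay")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.iti_range
        if lo < 0 or lo > hi:
            raise ValueError("iti_range must satisfy 0 <= min <= max")
        if self.fs <= 2 * self.erd_band[1]:
            raise ValueError("fs must exceed twice the upper ERD band edge")
        if self.effect_window[0] >= self.effect_window[1]:
            raise ValueError("effect_window start must precede end")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator injected, for use as a test oracle."""

    labels: np.ndarray
    stim_times: np.ndarray
    move_times: np.ndarray
    effect_topographies: dict[str, np.ndarray]
    informative_channels: list[str]
    erd_topographies: dict[str, np.ndarray] | None = None
    blink_topography: np.ndarray | None = None
    blink_times: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.stim_times) == len(self.move_times) == n):
            raise ValueError("labels, stim_times, move_times must align")
        if np.any(np.asarray(self.move_times) <= np.asarray(self.stim_times)):
            raise ValueError("movement must follow the stimulus")

    @property
    def discriminative_topography(self) -> np.ndarray:
        """Channel pattern of the right-minus-left slow-shift contrast."""
        return self.effect_topographies["R"] - self.effect_topographies["L"]


@dataclass
class Leadfield:
    """Forward gain from dipolar sources (3 free orientations) to channels."""

    gain: np.ndarray  # (n_channels, n_sources, 3)
    source_positions: np.ndarray  # (n_sources, 3)
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValueError("gain must have shape (channels, sources, 3)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")
        row_norms = np.linalg.norm(self.gain.reshape(self.gain.shape[0], -1), axis=1)
        if np.any(row_norms == 0):
            raise ValueError("gain has an all-zero channel row")


def generate_labels(
    n_trials: int,
    p_right: float = 0.5,
    p_stay: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sequentially biased hand choices from a two-state Markov chain.

    The first label is right with probability ``p_right``; each subsequent
    label repeats the previous one with probability ``p_stay``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for p, name in ((p_right, "p_right"), (p_stay, "p_stay")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n_trials)
    labels = np.empty(n_trials, dtype="<U1")
    labels[0] = "R" if u[0] < p_right else "L"
    for i in range(1, n_trials):
        labels[i] = labels[i - 1] if u[i] < p_stay else ("L" if labels[i - 1] == "R" else "R")
    return labels


def _one_over_f_noise(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f amplitude spectrum."""
    spec = np.fft.rfft(rng.standard_normal(n_samples))
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f[0] = f[1] if len(f) > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=n_samples)
    return x / x.std()


def _band_noise(
    rng: np.random.Generator, n_samples: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    taps = signal.firwin(int(fs * 0.4) | 1, band, fs=fs, pass_zero=False)
    x = signal.fftconvolve(rng.standard_normal(n_samples + len(taps)), taps, mode="same")
    x = x[len(taps) // 2 : len(taps) // 2 + n_samples]
    return x / x.std()


def _gaussian_topography(pos: np.ndarray, center: np.ndarray, sigma: float = 0.045) -> np.ndarray:
    d2 = np.sum((pos - center) ** 2, axis=1)
    topo = np.exp(-d2 / (2 * sigma**2))
    return topo / topo.max()


def _plateau(n: int, fs: float, ramp_s: float = 0.05) -> np.ndarray:
    """Unit plateau with raised-cosine onset/offset ramps."""
    r = min(int(round(ramp_s * fs)), max(n // 4, 1))
    prof = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r)) if r > 0 else np.ones(0)
    prof[:r] = ramp
    prof[n - r :] = ramp[::-1]
    return prof


def _effect_centers(
    channel_names: list[str], pos: np.ndarray, record: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Centers of the left/right-hemisphere effect topographies.

    Prefers C1/C2; when absent, falls back to the two most lateral
    frontocentral channels (one per hemisphere) and records a warning.
    """
    if "C1" in channel_names and "C2" in channel_names:
        return pos[channel_names.index("C1")], pos[channel_names.index("C2")]
    frontocentral = [
        i
        for i, ch in enumerate(channel_names)
        if ch.rstrip("h").rstrip("0123456789").rstrip("h") in ("FC", "FCC", "C")
    ]
    if not frontocentral:
        frontocentral = list(range(len(channel_names)))
    fc = np.array(frontocentral)
    left = fc[pos[fc, 0] < 0]
    right = fc[pos[fc, 0] > 0]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("cannot place effect topographies: no lateral channels")
    i_left = left[np.argmax(np.abs(pos[left, 0]))]
    i_right = right[np.argmax(np.abs(pos[right, 0]))]
    msg = (
        "C1/C2 not in montage; effect topographies centered on "
        f"{channel_names[i_left]}/{channel_names[i_right]}"
    )
    warnings.warn(msg)
    record.append(msg)
    return pos[i_left], pos[i_right]


def generate_session(config: SyntheticConfig) -> tuple[Recording, GroundTruth]:
    """Generate one continuous EEG/EMG session with ground truth.

    Timing model: the first stimulus occurs after a 3 s lead-in; each
    subsequent stimulus follows the previous one by
    ``config.dwell_s + U(iti_range)`` seconds, and 3 s of signal trail the
    last stimulus (so ±2.5 s epochs are always extractable).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    names = cfg.channel_names
    n_ch = len(names)
    pos = channel_positions(names)
    warn_record: list[str] = []

    labels = generate_labels(cfg.n_trials, cfg.p_right, cfg.p_stay, rng)

    gaps = cfg.dwell_s + rng.uniform(cfg.iti_range[0], cfg.iti_range[1], cfg.n_trials - 1)
    stim_times = 3.0 + np.concatenate([[0.0], np.cumsum(gaps)])
    duration = stim_times[-1] + 3.0
    n_samples = int(round(duration * fs))

    # movement onsets: lognormal latency with the configured median
    med_ms, log_sd = cfg.movement_latency
    lat = np.exp(np.log(med_ms / 1000.0) + log_sd * rng.standard_normal(cfg.n_trials))
    lat = np.clip(lat, 0.12, cfg.dwell_s)
    move_times = stim_times + lat

    # --- background: 1/f noise per channel + ongoing alpha -----------------
    data = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        data[c] = cfg.background_rms_uV * _one_over_f_noise(rng, n_samples, fs)
    alpha = _band_noise(rng, n_samples, fs, (9.0, 11.0))
    post = int(np.argmin(pos[:, 1]))  # most posterior channel
    alpha_topo = _gaussian_topography(pos, pos[post], sigma=0.06)
    data += cfg.alpha_rms_uV * np.outer(alpha_topo, alpha)

    # --- lateralized effect topographies ------------------------------------
    c_left, c_right = _effect_centers(names, pos, warn_record)
    topo_left = _gaussian_topography(pos, c_left)  # left hemisphere (e.g. C1)
    topo_right = _gaussian_topography(pos, c_right)

    # ERD/ERS: hemisphere-specific band-limited carriers with per-trial gain
    carrier_l = _band_noise(rng, n_samples, fs, cfg.erd_band)
    carrier_r = _band_noise(rng, n_samples, fs, cfg.erd_band)
    gain_l = np.ones(n_samples)
    gain_r = np.ones(n_samples)
    shift = np.zeros(n_samples)

    depth = min(0.9, 0.4 * cfg.effect_snr)
    shift_amp = cfg.slow_shift_uV * cfg.effect_snr
    w0, w1 = cfg.effect_window
    for t0, hand in zip(stim_times, labels):
        i0 = int(round((t0 + w0 / 1000.0) * fs))
        i1 = int(round((t0 + w1 / 1000.0) * fs))
        i0, i1 = max(i0, 0), min(i1, n_samples)
        if i1 <= i0:
            continue
        prof = _plateau(i1 - i0, fs)
        sgn = 1.0 if hand == "R" else -1.0
        # contralateral ERD (power down), ipsilateral ERS (power up)
        gain_l[i0:i1] *= 1.0 - sgn * depth * prof
        gain_r[i0:i1] *= 1.0 + sgn * depth * prof
        shift[i0:i1] += sgn * shift_amp * prof

    data += cfg.carrier_rms_uV * np.outer(topo_left, gain_l * carrier_l)
    data += cfg.carrier_rms_uV * np.outer(topo_right, gain_r * carrier_r)
    diff_topo = topo_left - topo_right
    data += np.outer(diff_topo, shift)

    # per-hand slow-shift channel patterns (what a decoder should recover)
    effect_topos = {"R": shift_amp * diff_topo, "L": -shift_amp * diff_topo}
    informative = [
        names[i] for i in np.flatnonzero(np.abs(diff_topo) > 0.5 * np.abs(diff_topo).max())
    ]

    # --- ocular artifacts ----------------------------------------------------
    blink_topo = None
    blink_times = np.array([])
    if cfg.artifact_rate > 0:
        n_blinks = rng.poisson(cfg.artifact_rate * duration / 60.0)
        blink_times = np.sort(rng.uniform(1.0, duration - 1.0, n_blinks))
        anterior = [ch for ch in ("AFp1", "AFp2") if ch in names]
        if anterior:
            center = pos[[names.index(ch) for ch in anterior]].mean(axis=0)
        else:
            center = pos[int(np.argmax(pos[:, 1]))]
        blink_topo = _gaussian_topography(pos, center, sigma=0.05)
        pulse = signal.windows.hann(int(0.4 * fs) | 1)
        blink = np.zeros(n_samples)
        for bt in blink_times:
            i = int(round(bt * fs))
            j0, j1 = i - len(pulse) // 2, i + len(pulse) // 2 + 1
            s0, s1 = max(j0, 0), min(j1, n_samples)
            blink[s0:s1] += 80.0 * pulse[s0 - j0 : s1 - j0]
        data += np.outer(blink_topo, blink)

    # --- EMG ----------------------------------------------------------------
    emg = 2.0 * rng.standard_normal((2, n_samples))
    burst_env = signal.windows.hann(int(0.35 * fs) | 1)
    for mt, hand in zip(move_times, labels):
        ch = 0 if hand == "L" else 1
        i = int(round(mt * fs))
        j1 = min(i + len(burst_env), n_samples)
        emg[ch, i:j1] += 50.0 * burst_env[: j1 - i] * rng.standard_normal(j1 - i)

    rec = Recording(
        data=data,
        fs=fs,
        channel_names=names,
        events=stim_times,
        labels=labels,
        emg=emg,
        emg_names=list(_EMG_NAMES),
    )
    truth = GroundTruth(
        labels=labels,
        stim_times=stim_times,
        move_times=move_times,
        effect_topographies=effect_topos,
        informative_channels=informative,
        erd_topographies={"left_hemisphere": topo_left, "right_hemisphere": topo_right},
        blink_topography=blink_topo,
        blink_times=blink_times,
        warnings=warn_record,
    )
    return rec, truth


def make_leadfield(
    n_channels: int,
    n_sources: int,
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> Leadfield:
    """Synthetic smooth leadfield (stand-in for a head-model forward solution).

    Each source/orientation produces a spatially smooth random channel
    pattern: white noise across channels filtered by a Gaussian kernel over
    channel positions. Reproducible under ``seed``.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rng = np.random.default_rng(seed)
    if channel_names is None:
        channel_names = list(DEFAULT_CHANNELS[:n_channels])
        if len(channel_names) < n_channels:
            raise ValueError(f"at most {len(DEFAULT_CHANNELS)} default channels available")
    elif len(channel_names) != n_channels:
        raise ValueError("channel_names length must equal n_channels")
    pos = channel_positions(channel_names)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    kernel = np.exp(-d2 / (2 * 0.04**2))
    src_pos = 0.07 * _random_unit_ball(rng, n_sources)
    gain = kernel @ rng.standard_normal((n_channels, n_sources * 3))
    gain = gain.reshape(n_channels, n_sources, 3)
    gain /= np.abs(gain).max()
    return Leadfield(gain=gain, source_positions=src_pos, channel_names=list(channel_names))


def _random_unit_ball(rng: np.random.Generator, n: int) -> np.ndarray:
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x * rng.random((n, 1)) ** (1 / 3)
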