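"""Shared fixtures: small synthetic sessions and hand-constructed epochs."""

from __future__ import annotations

import numpy as np
import pytest

from premove.containers import EpochSet
from premove.synthetic_data import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A short high-SNR session (60 trials, 250 Hz) with ground truth."""
    cfg = SyntheticConfig(n_trials=60, fs=250.0, effect_snr=2.0, seed=5)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    """Stimulus-locked ±2.5 s epochs of the small session (uncleaned)."""
    from premove.preprocessing import extract_epochs

    rec, _ = small_session
    return extract_epochs(rec)


def make_noise_epochs(
    n_trials: int = 40,
    n_channels: int = 8,
    fs: float = 250.0,
    t_lim_ms: tuple[float, float] = (-200.0, 200.0),
    seed: int = 0,
    channel_names: list[str] | None = None,
    labels: np.ndarray | None = None,
) -> EpochSet:
    """White-noise epochs with a short time axis, for fast unit tests."""
    rng = np.random.default_rng(seed)
    times = np.arange(round(t_lim_ms[0] / 1000 * fs), round(t_lim_ms[1] / 1000 * fs) + 1)
    times = times / fs * 1000.0
    if channel_names is None:
        channel_names = [f"CH{i}" for i in range(n_channels)]
    if labels is None:
        labels = np.array(["L", "R"] * (n_trials // 2) + ["L"] * (n_trials % 2))
    return EpochSet(
        data=rng.standard_normal((n_trials, len(channel_names), len(times))),
        times=times,
        fs=fs,
        channel_names=channel_names,
        labels=labels,
    )


def make_discriminable_epochs(
    n_per_class: int = 60,
    n_channels: int = 10,
    informative: tuple[int, ...] = (2, 5),
    amplitude: float = 3.0,
    effect_window_ms: tuple[float, float] = (-150.0, 150.0),
    fs: float = 250.0,
    t_lim_ms: tuple[float, float] = (-300.0, 200.0),
    distractor_sd: float = 0.0,
    seed: int = 0,
) -> tuple[EpochSet, np.ndarray]:
    """Noise epochs with a hand-dependent mean shift on selected channels.

    With ``distractor_sd > 0`` the two informative channels additionally
    carry a per-trial common distractor with opposite signs (+d and -d), so
    each is only moderately informative alone while their sum isolates the
    signal — decoding well requires *both* channels.

    Returns the epochs and the planted channel pattern (the right-minus-left
    discriminative topography).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(round(t_lim_ms[0] / 1000 * fs), round(t_lim_ms[1] / 1000 * fs) + 1)
    times = times / fs * 1000.0
    n = 2 * n_per_class
    labels = np.array(["L", "R"] * n_per_class)
    data = rng.standard_normal((n, n_channels, len(times)))
    pattern = np.zeros(n_channels)
    pattern[list(informative)] = 1.0
    tmask = (times >= effect_window_ms[0]) & (times <= effect_window_ms[1])
    signs = np.where(labels == "R", 1.0, -1.0)
    data += (
        signs[:, None, None]
        * amplitude
        * pattern[None, :, None]
        * tmask[None, None, :].astype(float)
    )
    if distractor_sd > 0:
        ch_a, ch_b = informative[0], informative[1]
        distractor = distractor_sd * rng.standard_normal(n)
        data[:, ch_a, :] += distractor[:, None] * tmask[None, :].astype(float)
        data[:, ch_b, :] -= distractor[:, None] * tmask[None, :].astype(float)
    epochs = EpochSet(
        data=data,
        times=times,
        fs=fs,
        channel_names=[f"CH{i}" for i in range(n_channels)],
        labels=labels,
    )
    return epochs, pattern
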