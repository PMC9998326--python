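"""In-memory containers for continuous recordings and stimulus-locked epochs.

All signal amplitudes are in microvolts; times are in seconds for continuous
data and in milliseconds relative to stimulus onset (t = 0) for epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """Continuous multichannel EEG (+ optional bipolar EMG) with events.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique 10-5 channel labels, one per row of ``data``.
    events : ndarray, shape (n_trials,)
        Visual-stimulus onset times in seconds, strictly increasing.
    labels : ndarray, shape (n_trials,)
        Upcoming hand per trial, ``"L"`` or ``"R"``.
    emg : ndarray, shape (n_emg, n_samples), optional
        Bipolar EMG channels (same sampling rate).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: np.ndarray
    labels: np.ndarray
    emg: np.ndarray | None = None
    emg_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ValueError("events must be strictly increasing")
        if len(self.labels) != len(self.events):
            raise ValueError("one label per event required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            events=self.events.copy(),
            labels=self.labels.copy(),
            emg=None if self.emg is None else self.emg.copy(),
            emg_names=list(self.emg_names),
        )


@dataclass
class EpochSet:
    """Trials x channels x time array, time-locked to stimulus onset.

    ``times`` is in milliseconds with t = 0 at the visual-stimulus sample.
    ``reference`` records the referencing state: ``"none"`` (as recorded),
    ``"average"``, or a channel label.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channel_names: list[str]
    labels: np.ndarray
    reference: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        n, c, t = self.data.shape
        if len(self.channel_names) != c:
            raise ValueError("channel_names length does not match data")
        if len(self.times) != t:
            raise ValueError("times length does not match data")
        if len(self.labels) != n:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            channel_names=list(self.channel_names),
        )

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask of samples with ``start_ms <= t < end_ms``.

        Analysis windows are half-open so that a window ending at 0 ms uses
        strictly pre-stimulus samples (the causal contract of the pre-visual
        mode).
        """
        return (self.times >= start_ms) & (self.times < end_ms)

    def window_data(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Copy of the data restricted to the half-open window [start, end)."""
        mask = self.time_mask(start_ms, end_ms)
        if not mask.any():
            raise ValueError(
                f"window ({start_ms}, {end_ms}) ms lies outside the epoch "
                f"({self.times[0]:.1f}, {self.times[-1]:.1f}) ms"
            )
        return self.data[:, :, mask].copy()

    @property
    def pre_mask(self) -> np.ndarray:
        """Mask of strictly pre-stimulus samples (t < 0)."""
        return self.times < 0

    def select_channels(self, names: list[str]) -> "EpochSet":
        """Return a new :class:`EpochSet` restricted to ``names`` (in order)."""
        missing = [ch for ch in names if ch not in self.channel_names]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        idx = [self.channel_names.index(ch) for ch in names]
        return replace(
            self,
            data=self.data[:, idx, :].copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            channel_names=list(names),
        )

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx].copy(),
            times=self.times.copy(),
            labels=self.labels[idx].copy(),
            channel_names=list(self.channel_names),
        )
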