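"""Readers and writers for standard formats and the HDF5 containers.

Continuous signals import from EDF and BrainVision (via mne) or from the
package's own HDF5 container; event tables are delimited text with columns
``trial, stim_time_s, move_time_s, hand``. Epochs round-trip through HDF5
(datasets ``/data``, ``/times``, ``/labels``, ``/channels``; attributes
``fs``, ``reference``).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from premove.containers import EpochSet, Recording

__all__ = [
    "read_recording",
    "read_events_csv",
    "write_events_csv",
    "write_recording_h5",
    "read_recording_h5",
    "write_epochs_h5",
    "read_epochs_h5",
]


def read_events_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stim_times_s, labels, move_times_s) from a delimited event table."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"stim_time_s", "hand"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table needs columns {sorted(required)}, got {list(df.columns)}")
    move = df["move_time_s"].to_numpy(float) if "move_time_s" in df else np.full(len(df), np.nan)
    return df["stim_time_s"].to_numpy(float), df["hand"].astype(str).to_numpy(), move


def write_events_csv(path, stim_times, labels, move_times=None) -> None:
    n = len(stim_times)
    pd.DataFrame(
        {
            "trial": np.arange(n),
            "stim_time_s": np.asarray(stim_times, float),
            "move_time_s": np.full(n, np.nan) if move_times is None else np.asarray(move_times),
            "hand": np.asarray(labels),
        }
    ).to_csv(path, index=False)


def read_recording(path, events_csv=None) -> Recording:
    """Import a continuous recording from EDF, BrainVision (.vhdr) or HDF5.

    For EDF/BrainVision an event table (``events_csv``) supplies stimulus
    times and hand labels. Signal units are converted to microvolts.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".h5":
        return read_recording_h5(path)
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif suffix == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported format {suffix!r} (use .edf, .vhdr or .h5)")
    if events_csv is None:
        raise ValueError("an event table (events_csv) is required for EDF/BrainVision input")
    stim, labels, _ = read_events_csv(events_csv)
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=stim,
        labels=labels,
    )


def write_recording_h5(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("events", data=rec.events)
        f.create_dataset("labels", data=np.asarray(rec.labels, dtype="S1"))
        f.create_dataset("channels", data=np.array(rec.channel_names, dtype="S"))
        if rec.emg is not None:
            f.create_dataset("emg", data=rec.emg)
            f.create_dataset("emg_names", data=np.array(rec.emg_names, dtype="S"))
        f.attrs["fs"] = rec.fs
        f.attrs["kind"] = "recording"


def read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_names=[c.decode() for c in f["channels"][()]],
            events=f["events"][()],
            labels=np.array([c.decode() for c in f["labels"][()]]),
            emg=f["emg"][()] if "emg" in f else None,
            emg_names=[c.decode() for c in f["emg_names"][()]] if "emg_names" in f else [],
        )


def write_epochs_h5(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype="S1"))
        f.create_dataset("channels", data=np.array(epochs.channel_names, dtype="S"))
        f.attrs["fs"] = epochs.fs
        f.attrs["reference"] = epochs.reference
        f.attrs["kind"] = "epochs"


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            fs=float(f.attrs["fs"]),
            channel_names=[c.decode() for c in f["channels"][()]],
            labels=np.array([c.decode() for c in f["labels"][()]]),
            reference=str(f.attrs["reference"]),
        )
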