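"""Causal calibrate-then-stream simulation of real-time deployment.

The classifier is calibrated on each participant's first ``n`` right-hand
and first ``n`` left-hand trials; every trial after the last calibration
index is then classified in chronological order, with no reshuffling and no
rebalancing of the test stream. Two window modes are provided:
``pre_movement`` (−150…+150 ms around the visual stimulus) and
``pre_visual`` (−150…0 ms, usable when the EEG must control stimulus
timing — no post-stimulus sample is touched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from premove.classification import fit_logistic_cv
from premove.containers import EpochSet
from premove.features import WindowSpec, fit_feature_ica, ica_features

__all__ = ["RealtimeResult", "simulate_realtime", "MODE_WINDOWS"]

MODE_WINDOWS = {
    "pre_movement": WindowSpec(-150.0, 150.0),
    "pre_visual": WindowSpec(-150.0, 0.0),
}

#: Minimum number of testable trials for a result to count (else flagged).
MIN_TEST_TRIALS = 25


@dataclass
class RealtimeResult:
    predictions: np.ndarray
    trial_indices: np.ndarray
    labels: np.ndarray
    accuracy: float
    balanced_accuracy: float
    n_calibration_trials: int
    n_test_trials: int
    mode: str
    excluded: bool
    last_calibration_index: int
    metadata: dict = field(default_factory=dict)


def simulate_realtime(
    epochs: EpochSet,
    labels=None,
    mode: str = "pre_movement",
    n_calib_per_class: int = 100,
    m: int = 30,
    seed: int = 0,
    min_test_trials: int = MIN_TEST_TRIALS,
    **clf_kwargs,
) -> RealtimeResult:
    """Calibrate on the earliest trials, then classify the rest in order.

    ``epochs`` must be in chronological order. Calibration uses the first
    ``n_calib_per_class`` occurrences of each class; trials of the opposite
    class interleaved before the last calibration index are not tested.
    The test stream is scored as-is (plain accuracy) and additionally as
    balanced accuracy, since the stream need not be balanced. Results with
    fewer than ``min_test_trials`` testable trials are flagged ``excluded``.
    """
    if mode not in MODE_WINDOWS:
        raise ValueError(f"mode must be one of {sorted(MODE_WINDOWS)}")
    labels = np.asarray(epochs.labels if labels is None else labels)
    calib_idx = []
    for c in ("L", "R"):
        occ = np.flatnonzero(labels == c)
        if len(occ) < n_calib_per_class:
            raise ValueError(
                f"insufficient calibration trials for class {c!r}: "
                f"{len(occ)} available, {n_calib_per_class} required"
            )
        calib_idx.append(occ[:n_calib_per_class])
    calib_idx = np.sort(np.concatenate(calib_idx))
    last_calib = int(calib_idx[-1])
    test_idx = np.arange(last_calib + 1, epochs.n_trials)

    window = MODE_WINDOWS[mode]
    calib = epochs.select_trials(calib_idx)
    model = fit_feature_ica(calib, window, m, seed=seed)
    clf = fit_logistic_cv(ica_features(calib, model), labels[calib_idx], seed=seed, **clf_kwargs)

    if len(test_idx):
        test = epochs.select_trials(test_idx)
        preds = clf.predict(ica_features(test, model))
        truth = labels[test_idx]
        accuracy = float(np.mean(preds == truth))
        per_class = [np.mean(preds[truth == c] == c) for c in ("L", "R") if np.any(truth == c)]
        balanced = float(np.mean(per_class))
    else:
        preds = np.array([], dtype="<U1")
        truth = np.array([], dtype="<U1")
        accuracy = balanced = float("nan")

    return RealtimeResult(
        predictions=preds,
        trial_indices=test_idx,
        labels=truth,
        accuracy=accuracy,
        balanced_accuracy=balanced,
        n_calibration_trials=len(calib_idx),
        n_test_trials=len(test_idx),
        mode=mode,
        excluded=len(test_idx) < min_test_trials,
        last_calibration_index=last_calib,
        metadata={
            "window": (window.start_ms, window.end_ms),
            "m": m,
            "seed": seed,
            "lambda": clf.lam,
        },
    )
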