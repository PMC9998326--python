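"""Parameter-optimization procedures: time windows, channels, trial counts.

* :func:`enumerate_windows` / :func:`optimize_window` — grid of candidate
  analysis windows (sizes 600…50 ms shifted in 100 ms steps over
  −550…+150 ms) scored by mean held-out accuracy over repeated balanced
  80/20 splits (split seeds shared across windows for a paired comparison).
* :func:`greedy_channel_selection` / :func:`channel_points` /
  :func:`aggregate_group_ranking` — forward channel selection scored by
  cross-validated accuracy, point banding of the resulting ranks
  (#1–5 → 5, #6–15 → 3, #16–30 → 2, #31–50 → 1, >#50 → 0), and group-level
  aggregation with mean imputation for channels a subject is missing,
  normalized to 0–100 against the best channel.
* :func:`learning_curve` — accuracy versus training-set size (10, 30, 50, …
  per class) against a fixed-size held-out set, averaged over reshuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from premove.classification import evaluate, fit_logistic_cv, prepare_datasets
from premove.containers import EpochSet
from premove.features import (
    WindowSpec,
    fit_feature_ica,
    fit_spatiotemporal_pca,
    ica_features,
    st_features,
)

__all__ = [
    "WindowGrid",
    "ChannelRanking",
    "LearningCurve",
    "enumerate_windows",
    "optimize_window",
    "greedy_channel_selection",
    "channel_points",
    "aggregate_group_ranking",
    "learning_curve",
    "DEFAULT_WINDOW_SIZES",
]

DEFAULT_WINDOW_SIZES = (600, 500, 400, 300, 200, 150, 100, 50)


@dataclass
class WindowGrid:
    sizes: tuple
    step: float
    anchor_start: float
    max_end: float
    windows: list[WindowSpec]

    def __len__(self) -> int:
        return len(self.windows)


def enumerate_windows(
    sizes=DEFAULT_WINDOW_SIZES,
    step: float = 100.0,
    anchor_start: float = -550.0,
    max_end: float = 150.0,
) -> WindowGrid:
    """All windows of each size, anchored at ``anchor_start`` and shifted by
    ``step`` while the window end stays within ``max_end``."""
    span = max_end - anchor_start
    windows: list[WindowSpec] = []
    for s in sizes:
        if s > span:
            warnings.warn(f"window size {s} ms exceeds the {span} ms span; skipped")
            continue
        k = 0
        while anchor_start + k * step + s <= max_end:
            start = anchor_start + k * step
            windows.append(WindowSpec(start, start + s))
            k += 1
    return WindowGrid(
        sizes=tuple(sizes), step=step, anchor_start=anchor_start, max_end=max_end, windows=windows
    )


def _fit_and_score(
    train: EpochSet,
    test: EpochSet,
    window: WindowSpec,
    backend: str,
    m: int,
    seed: int,
    clf_kwargs: dict,
) -> tuple[float, float]:
    """(held-out accuracy, CV accuracy) for one split and window."""
    if backend == "ica":
        model = fit_feature_ica(train, window, m, seed=seed)
        f_tr, f_te = ica_features(train, model), ica_features(test, model)
    elif backend == "st_pca":
        basis = fit_spatiotemporal_pca(train, window, m)
        f_tr, f_te = st_features(train, basis), st_features(test, basis)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    clf = fit_logistic_cv(f_tr, train.labels, seed=seed, **clf_kwargs)
    acc, _ = evaluate(clf, f_te, test.labels)
    return acc, clf.cv_accuracy


def optimize_window(
    epochs: EpochSet,
    labels,
    grid: WindowGrid,
    n_shuffles: int = 20,
    backend: str = "ica",
    m: int = 30,
    seed: int = 0,
    **clf_kwargs,
) -> tuple[WindowSpec, dict[WindowSpec, float]]:
    """Mean held-out accuracy per window over shared balanced splits.

    Returns the argmax window and the full accuracy map. The same
    ``n_shuffles`` split seeds are reused for every window (paired
    comparison), which stabilizes the argmax.
    """
    labels = np.asarray(labels)
    splits = [prepare_datasets(labels, seed=seed + j) for j in range(n_shuffles)]
    acc = {w: 0.0 for w in grid.windows}
    for j, split in enumerate(splits):
        train = epochs.select_trials(split.train_indices)
        test = epochs.select_trials(split.test_indices)
        for w in grid.windows:
            a, _ = _fit_and_score(train, test, w, backend, m, seed + j, clf_kwargs)
            acc[w] += a / n_shuffles
    best = max(acc, key=lambda w: (acc[w], -w.start_ms))
    return best, acc


@dataclass
class ChannelRanking:
    """Selection order with banded points and 0–100 normalized scores."""

    order: list[str]
    points: dict[str, float]
    normalized: dict[str, float]
    checkpoint_accuracy: dict[int, float] = field(default_factory=dict)


def _selection_checkpoints(n_channels: int) -> list[int]:
    """Set sizes at which selection accuracy is recorded: +1 to 5, +3 to <30,
    +5 thereafter (final block truncated)."""
    sizes = list(range(1, min(5, n_channels) + 1))
    while sizes[-1] < n_channels:
        step = 3 if sizes[-1] < 30 else 5
        sizes.append(min(sizes[-1] + step, n_channels))
    return sizes


def greedy_channel_selection(
    epochs: EpochSet,
    labels,
    window: WindowSpec = WindowSpec(-150, 150),
    m: int = 30,
    seed: int = 0,
    max_channels: int | None = None,
    **clf_kwargs,
) -> ChannelRanking:
    """Forward channel selection ranked by cross-validated accuracy.

    Each step appends the single candidate channel whose addition maximizes
    the 5-fold CV accuracy of the ICA-feature classifier on the provided
    (training) trials; block additions (+3, then +5) are realized as nested
    single-channel greedy steps, so the selection order is the full greedy
    permutation while accuracies are recorded at the block checkpoints.
    Ties break by channel-name lexicographic order. ``max_channels`` stops
    selection early (a truncated ranking: remaining channels unranked).
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    labels = np.asarray(labels)
    all_names = list(epochs.channel_names)
    limit = len(all_names) if max_channels is None else min(max_channels, len(all_names))
    checkpoints = [s for s in _selection_checkpoints(len(all_names)) if s <= limit]

    selected: list[str] = []
    remaining = sorted(all_names)  # lexicographic scan order = tie-break
    checkpoint_acc: dict[int, float] = {}
    while len(selected) < limit:
        best_ch, best_acc = None, -np.inf
        for ch in remaining:
            sub = epochs.select_channels(selected + [ch])
            model = fit_feature_ica(sub, window, m, seed=seed)
            feats = ica_features(sub, model)
            clf = fit_logistic_cv(feats, labels, seed=seed, **clf_kwargs)
            if clf.cv_accuracy > best_acc:
                best_ch, best_acc = ch, clf.cv_accuracy
        selected.append(best_ch)
        remaining.remove(best_ch)
        if len(selected) in checkpoints:
            checkpoint_acc[len(selected)] = best_acc

    points = channel_points(selected)
    top = max(points.values()) or 1.0
    normalized = {ch: 100.0 * p / top for ch, p in points.items()}
    return ChannelRanking(
        order=selected, points=points, normalized=normalized, checkpoint_accuracy=checkpoint_acc
    )


def channel_points(order) -> dict[str, float]:
    """Banded points by rank: #1–5 → 5, #6–15 → 3, #16–30 → 2, #31–50 → 1,
    beyond #50 → 0."""
    pts = {}
    for rank, ch in enumerate(order, start=1):
        if rank <= 5:
            p = 5
        elif rank <= 15:
            p = 3
        elif rank <= 30:
            p = 2
        elif rank <= 50:
            p = 1
        else:
            p = 0
        pts[ch] = float(p)
    return pts


def aggregate_group_ranking(per_subject_points: list[dict[str, float]]) -> ChannelRanking:
    """Sum subject points per channel; a subject missing a channel contributes
    the mean of the subjects that have it. Scores normalized to 0–100."""
    if not per_subject_points:
        raise ValueError("need at least one subject")
    channels = sorted({ch for pts in per_subject_points for ch in pts})
    totals: dict[str, float] = {}
    for ch in channels:
        have = [pts[ch] for pts in per_subject_points if ch in pts]
        if not have:
            warnings.warn(f"channel {ch} missing in all subjects; excluded")
            continue
        imputed = float(np.mean(have))
        totals[ch] = sum(pts.get(ch, imputed) for pts in per_subject_points)
    top = max(totals.values())
    normalized = {ch: 100.0 * v / top if top > 0 else 0.0 for ch, v in totals.items()}
    order = sorted(totals, key=lambda ch: (-totals[ch], ch))
    return ChannelRanking(order=order, points=totals, normalized=normalized)


@dataclass
class LearningCurve:
    n_per_class: np.ndarray
    mean_accuracy: np.ndarray
    std_accuracy: np.ndarray
    n_shuffles: int


def learning_curve(
    epochs: EpochSet,
    labels,
    window: WindowSpec = WindowSpec(-150, 150),
    start: int = 10,
    step: int = 20,
    holdout_per_class: int = 20,
    n_shuffles: int = 20,
    m: int = 30,
    seed: int = 0,
    **clf_kwargs,
) -> LearningCurve:
    """Held-out accuracy versus balanced training-set size.

    Training sizes run ``start, start+step, …`` per class up to the minority
    class count minus ``holdout_per_class``; each point is tested against
    ``2 * holdout_per_class`` held-out trials, averaged over ``n_shuffles``
    reshuffles. Truncates (with a warning) when trials run short.
    """
    labels = np.asarray(labels)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in ("L", "R")}
    n_min = min(len(v) for v in idx_by_class.values())
    max_train = n_min - holdout_per_class
    if max_train < start:
        raise ValueError("insufficient trials for the requested schedule")
    sizes = np.arange(start, max_train + 1, step)
    if sizes[-1] < max_train and len(sizes) == 0:
        warnings.warn("curve truncated: insufficient trials")
    accs = np.zeros((len(sizes), n_shuffles))
    rng_master = np.random.default_rng(seed)
    for j in range(n_shuffles):
        rng = np.random.default_rng(rng_master.integers(2**31))
        perm = {c: rng.permutation(v) for c, v in idx_by_class.items()}
        test_idx = np.concatenate([perm[c][:holdout_per_class] for c in ("L", "R")])
        test = epochs.select_trials(np.sort(test_idx))
        for i, n in enumerate(sizes):
            train_idx = np.concatenate(
                [perm[c][holdout_per_class : holdout_per_class + n] for c in ("L", "R")]
            )
            train = epochs.select_trials(np.sort(train_idx))
            acc, _ = _fit_and_score(train, test, window, "ica", m, seed + j, clf_kwargs)
            accs[i, j] = acc
    return LearningCurve(
        n_per_class=sizes,
        mean_accuracy=accs.mean(axis=1),
        std_accuracy=accs.std(axis=1),
        n_shuffles=n_shuffles,
    )
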