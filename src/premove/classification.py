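"""Balanced splits and regularized logistic regression with a CV lambda grid.

The classifier minimizes the mean logistic loss plus ``lambda * penalty``
(L1 for ICA features, L2 for spatiotemporal PCA features), with lambda
selected by 5-fold cross-validation over 30 geometrically spaced values in
``[1e-5 / n_trials, 1e5 / n_trials]``. Features are standardized with
training statistics before fitting; class encoding is L -> -1, R -> +1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from premove.features import FeatureMatrix

__all__ = [
    "DataSplit",
    "ClassifierModel",
    "prepare_datasets",
    "lambda_grid",
    "fit_penalized_logistic",
    "fit_logistic_cv",
    "evaluate",
    "encode_labels",
]

CLASSES = ("L", "R")  # encoded as -1, +1


def encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return np.where(labels == "R", 1, -1)


@dataclass
class DataSplit:
    """Class-balanced train/test indices into the original trial order."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")


def prepare_datasets(labels, test_frac: float = 0.2, seed: int = 0) -> DataSplit:
    """Balance classes by subsampling, then split 80/20 within each class.

    The majority class is randomly subsampled (without replacement) to the
    minority count, so both partitions contain exactly 50% of each class.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in CLASSES}
    counts = {c: len(v) for c, v in idx_by_class.items()}
    n_min = min(counts.values())
    if n_min < 2:
        raise ValueError(f"need at least 2 trials per class, got {counts}")
    if n_min < 50:
        warnings.warn(f"fewer than 50 trials in a class ({counts}); results may be unstable")
    n_test = int(round(test_frac * n_min))
    if n_test < 1 or n_test >= n_min:
        raise ValueError("test_frac leaves an empty partition")
    train, test = [], []
    for c in CLASSES:
        sel = rng.permutation(idx_by_class[c])[:n_min]
        test.append(sel[:n_test])
        train.append(sel[n_test:])
    return DataSplit(
        train_indices=np.sort(np.concatenate(train)),
        test_indices=np.sort(np.concatenate(test)),
        seed=seed,
    )


def lambda_grid(n_trials: int, n_values: int = 30) -> np.ndarray:
    """Geometric grid of ``n_values`` regularization coefficients.

    Endpoints are ``1e-5 / n_trials`` and ``1e5 / n_trials`` inclusive,
    ascending.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return np.geomspace(1e-5 / n_trials, 1e5 / n_trials, n_values)


def fit_penalized_logistic(
    x: np.ndarray,
    y: np.ndarray,
    penalty: str,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
    coef_init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize ``mean(log(1 + exp(-y f))) + lam * P(w)`` at a fixed lambda.

    ``P`` is ``||w||_1`` or ``0.5 ||w||_2^2``; the intercept is not
    penalized. Returns ``(weights, intercept)``. ``x`` is used as given
    (standardize beforehand).
    """
    if penalty not in ("l1", "l2"):
        raise ValueError("penalty must be 'l1' or 'l2'")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    n = x.shape[0]
    est = LogisticRegression(
        l1_ratio=1.0 if penalty == "l1" else 0.0,
        C=1.0 / (n * lam),
        solver="saga",
        tol=tol,
        max_iter=max_iter,
        fit_intercept=True,
        random_state=0,
        warm_start=coef_init is not None,
    )
    if coef_init is not None:
        est.coef_ = coef_init[0].reshape(1, -1).copy()
        est.intercept_ = np.array([coef_init[1]], dtype=float)
        est.classes_ = np.array([-1, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x, y)
    return est.coef_.ravel().copy(), float(est.intercept_[0])


@dataclass
class ClassifierModel:
    """Linear classifier with standardization stats and the CV record."""

    weights: np.ndarray
    intercept: float
    penalty: str
    lam: float
    cv_curve: np.ndarray  # (n_lambdas, 2): lambda, mean CV logistic loss
    cv_accuracy: float  # mean CV accuracy at the selected lambda
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_backend: str = "ica"
    learner: str = "logistic"
    metadata: dict = field(default_factory=dict)

    def decision_scores(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        if x.shape[1] != len(self.weights):
            raise ValueError("feature dimension does not match the model")
        z = (x - self.scaler_mean) / self.scaler_scale
        return z @ self.weights + self.intercept

    def predict(self, features) -> np.ndarray:
        return np.where(self.decision_scores(features) > 0, "R", "L")


def _logistic_loss(y: np.ndarray, scores: np.ndarray) -> float:
    return float(np.mean(np.logaddexp(0.0, -y * scores)))


def fit_logistic_cv(
    features: FeatureMatrix | np.ndarray,
    labels,
    penalty: str | None = None,
    k: int = 5,
    seed: int = 0,
    n_lambdas: int = 30,
    tol: float = 1e-7,
    max_iter: int = 1000,
    learner: str = "logistic",
    standardize: bool = True,
) -> ClassifierModel:
    """K-fold CV over the lambda grid, then refit at the selected lambda.

    The lambda minimizing the mean CV logistic loss is selected (ties broken
    toward the largest lambda, i.e. the most parsimonious model) and the
    model is refit on all provided trials. ``penalty`` defaults to L1 for
    ICA features and L2 for spatiotemporal PCA features. ``learner="svm"``
    substitutes a hinge-loss (linear SVM) learner with the same grid.
    """
    if isinstance(features, FeatureMatrix):
        backend = features.backend
        x = features.values
    else:
        backend = "unknown"
        x = np.asarray(features, dtype=float)
    if penalty is None:
        penalty = "l1" if backend == "ica" else "l2"
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    y = encode_labels(labels)
    n = x.shape[0]

    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mu = np.zeros(x.shape[1])
        sd = np.ones(x.shape[1])
    z = (x - mu) / sd

    lams = lambda_grid(n, n_lambdas)
    order = np.argsort(lams)[::-1]  # strong-to-weak for warm starts
    cv_loss = np.zeros(len(lams))
    cv_acc = np.zeros(len(lams))

    folds = _stratified_folds(y, k, seed)
    for tr, va in folds:
        init = None
        for j in order:
            if learner == "svm":
                w, b = _fit_hinge(z[tr], y[tr], lams[j], tol, max_iter)
            else:
                w, b = fit_penalized_logistic(
                    z[tr], y[tr], penalty, lams[j], tol, max_iter, coef_init=init
                )
                init = (w, b)
            s = z[va] @ w + b
            cv_loss[j] += _logistic_loss(y[va], s) / k
            cv_acc[j] += float(np.mean(np.sign(s) == y[va])) / k

    best_loss = cv_loss.min()
    candidates = np.flatnonzero(cv_loss <= best_loss * (1 + 1e-12))
    j_best = candidates[np.argmax(lams[candidates])]

    if learner == "svm":
        w, b = _fit_hinge(z, y, lams[j_best], tol, max_iter)
    else:
        w, b = fit_penalized_logistic(z, y, penalty, lams[j_best], tol, max_iter)
    return ClassifierModel(
        weights=w,
        intercept=b,
        penalty=penalty,
        lam=float(lams[j_best]),
        cv_curve=np.column_stack([lams, cv_loss]),
        cv_accuracy=float(cv_acc[j_best]),
        scaler_mean=mu,
        scaler_scale=sd,
        feature_backend=backend,
        learner=learner,
        metadata={"k": k, "seed": seed, "n_trials": n},
    )


def _stratified_folds(y: np.ndarray, k: int, seed: int, max_refolds: int = 10):
    """Stratified K-fold; refold with a new seed on a degenerate fold."""
    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both classes present")


def _fit_hinge(z, y, lam, tol, max_iter) -> tuple[np.ndarray, float]:
    est = LinearSVC(C=1.0 / (len(y) * lam), tol=tol, max_iter=max(max_iter, 2000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(z, y)
    return est.coef_.ravel().copy(), float(est.intercept_[0])


def evaluate(model: ClassifierModel, features, labels) -> tuple[float, np.ndarray]:
    """Accuracy (fraction of correctly classified trials) and predictions."""
    preds = model.predict(features)
    labels = np.asarray(labels)
    return float(np.mean(preds == labels)), preds


def save_classifier_json(path, model: ClassifierModel) -> None:
    """Serialize a fitted classifier to JSON (weights, intercept, lambda,
    standardization statistics, CV curve, backend id)."""
    import json

    payload = {
        "weights": model.weights.tolist(),
        "intercept": model.intercept,
        "penalty": model.penalty,
        "lambda": model.lam,
        "cv_curve": model.cv_curve.tolist(),
        "cv_accuracy": model.cv_accuracy,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "feature_backend": model.feature_backend,
        "learner": model.learner,
        "metadata": model.metadata,
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def load_classifier_json(path) -> ClassifierModel:
    import json

    with open(path) as f:
        d = json.load(f)
    return ClassifierModel(
        weights=np.asarray(d["weights"]),
        intercept=float(d["intercept"]),
        penalty=d["penalty"],
        lam=float(d["lambda"]),
        cv_curve=np.asarray(d["cv_curve"]),
        cv_accuracy=float(d["cv_accuracy"]),
        scaler_mean=np.asarray(d["scaler_mean"]),
        scaler_scale=np.asarray(d["scaler_scale"]),
        feature_backend=d["feature_backend"],
        learner=d["learner"],
        metadata=d.get("metadata", {}),
    )
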