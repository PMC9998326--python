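"""The recommended end-to-end pipeline: configuration, orchestration, I/O glue.

Defaults reproduce the recommended decoding setup: the 32-channel
sensorimotor montage referenced to CPz, a fixed −150…+150 ms window around
visual-stimulus onset, 30 independent components (fewer when fewer channels
survive), L1-regularized logistic regression with the cross-validated
lambda grid, and balanced 80/20 train/test evaluation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import numpy as np

from premove import __version__
from premove.classification import ClassifierModel, evaluate, fit_logistic_cv, prepare_datasets
from premove.containers import EpochSet, Recording
from premove.features import WindowSpec, fit_feature_ica, ica_features
from premove import preprocessing as pp

__all__ = [
    "PipelineConfig",
    "default_montage",
    "preprocess",
    "run_recommended",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


def default_montage() -> list[str]:
    """The recommended 32-channel montage shipped as an editable text file."""
    text = resources.files("premove").joinpath("data/montage32.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass
class PipelineConfig:
    """All knobs of the recommended pipeline, with reproducible defaults."""

    montage: list[str] = field(default_factory=default_montage)
    reference: str = "CPz"
    window: tuple[float, float] = (-150.0, 150.0)
    backend: str = "ica"
    m: int = 30
    n_calib_per_class: int = 100
    test_frac: float = 0.2
    seed: int = 0
    highpass_hz: float = 1.0
    lowpass_hz: float = 45.0
    epoch_pre_s: float = 2.5
    epoch_post_s: float = 2.5
    target_fs: float = 1000.0
    z_thresh: float = 3.5
    exclude_channels: tuple = ()
    clean_n_components: int = 50
    auto_ocular: bool = True
    clean_fit_decim: int = 4  # cleaning ICA fits on every 4th pre-stimulus sample
    standardize: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["montage"] = list(d["montage"])
        d["exclude_channels"] = list(d["exclude_channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "window" in d:
            d["window"] = tuple(d["window"])
        if "exclude_channels" in d:
            d["exclude_channels"] = tuple(d["exclude_channels"])
        return cls(**d)


def _fir_orders(fs: float) -> tuple[int, int]:
    """Filter orders scaled with the sampling rate: ~1 s of taps for the
    1 Hz high-pass, ~0.1 s for the 45 Hz low-pass."""
    return max(int(round(fs)), 10), max(int(round(0.1 * fs)), 10)


def preprocess(recording: Recording, config: PipelineConfig) -> tuple[EpochSet, dict]:
    """Continuous recording -> cleaned, referenced, montage-selected epochs.

    Chain: high-pass on the raw signal, stimulus-locked epoching, resampling
    to ``target_fs``, low-pass, pre-stimulus variance rejection, referencing,
    baseline correction, artifact-reduction ICA, montage selection. Montage
    channels absent from the *recording* raise an error; montage channels
    dropped by the cleaning are skipped with a warning.
    """
    unknown = [ch for ch in list(config.montage) + [config.reference]
               if ch not in recording.channel_names]
    if unknown:
        raise ValueError(f"montage channel(s) not in the recording: {unknown}")

    hp_order, lp_order = _fir_orders(recording.fs)
    rec = pp.fir_filter(recording, "highpass", config.highpass_hz, hp_order)
    epochs = pp.extract_epochs(rec, config.epoch_pre_s, config.epoch_post_s)
    if epochs.fs > config.target_fs:
        epochs = pp.resample_epochs(epochs, config.target_fs)
    _, lp_order = _fir_orders(epochs.fs)
    epochs = pp.fir_filter(epochs, "lowpass", config.lowpass_hz, lp_order)

    epochs, rejection = pp.reject_outliers(epochs, config.z_thresh, config.exclude_channels)
    if config.reference == "average":
        epochs = pp.rereference(epochs, "average")
    else:
        if config.reference not in epochs.channel_names:
            raise ValueError(f"reference channel {config.reference!r} was rejected")
        epochs = pp.rereference(epochs, config.reference)
    epochs = pp.baseline_correct(epochs)
    epochs, clean_model = pp.clean_ica(
        epochs,
        n_components=config.clean_n_components,
        remove="auto_ocular" if config.auto_ocular else [],
        seed=config.seed,
        fit_decim=config.clean_fit_decim,
    )

    available = [ch for ch in config.montage if ch in epochs.channel_names]
    dropped = [ch for ch in config.montage if ch not in epochs.channel_names]
    if dropped:
        warnings.warn(f"montage channel(s) removed during cleaning, skipped: {dropped}")
    epochs = epochs.select_channels(available)
    report = {
        "removed_channels": rejection.removed_channels,
        "removed_trials": [int(i) for i in rejection.removed_trials],
        "excluded_channels": rejection.excluded_channels,
        "cleaning_components_removed": clean_model.removed_components,
        "montage_dropped": dropped,
        "n_trials": epochs.n_trials,
        "channels": list(epochs.channel_names),
        "fs": epochs.fs,
    }
    return epochs, report


def run_recommended(recording_or_path, config: PipelineConfig | None = None):
    """Preprocess, balance/split, fit features + classifier, evaluate.

    Returns ``(report, artifacts)``: a JSON-serializable run report (test
    accuracy, per-trial predictions, all parameters and seeds) and the
    fitted objects (epochs, feature model, classifier).
    """
    config = config or PipelineConfig()
    if isinstance(recording_or_path, (str, Path)):
        from premove.io import read_recording

        recording = read_recording(recording_or_path)
    else:
        recording = recording_or_path

    epochs, prep_report = preprocess(recording, config)
    split = prepare_datasets(epochs.labels, config.test_frac, config.seed)
    train = epochs.select_trials(split.train_indices)
    test = epochs.select_trials(split.test_indices)

    window = WindowSpec(*config.window)
    if config.backend == "ica":
        fmodel = fit_feature_ica(train, window, config.m, seed=config.seed)
        f_train, f_test = ica_features(train, fmodel), ica_features(test, fmodel)
        penalty = "l1"
    elif config.backend == "st_pca":
        from premove.features import fit_spatiotemporal_pca, st_features

        fmodel = fit_spatiotemporal_pca(train, window, config.m)
        f_train, f_test = st_features(train, fmodel), st_features(test, fmodel)
        penalty = "l2"
    else:
        raise ValueError(f"unknown backend {config.backend!r}")

    clf = fit_logistic_cv(
        f_train, train.labels, penalty=penalty, seed=config.seed, standardize=config.standardize
    )
    accuracy, preds = evaluate(clf, f_test, test.labels)

    report = {
        "accuracy": accuracy,
        "n_train": train.n_trials,
        "n_test": test.n_trials,
        "predictions": preds.tolist(),
        "test_labels": test.labels.tolist(),
        "selected_lambda": clf.lam,
        "cv_accuracy": clf.cv_accuracy,
        "penalty": clf.penalty,
        "backend": config.backend,
        "window_ms": list(config.window),
        "n_components": getattr(fmodel, "n_components", config.m),
        "preprocessing": prep_report,
        "config": config.to_dict(),
        "package_version": __version__,
    }
    artifacts = {"epochs": epochs, "feature_model": fmodel, "classifier": clf, "split": split}
    return report, artifacts


def save_model(path, feature_model, classifier: ClassifierModel, config: PipelineConfig) -> None:
    """Serialize feature model + classifier + config to one HDF5 file."""
    from premove.features import FeatureICAModel, PCABasis

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["package_version"] = __version__
        g = f.create_group("feature")
        if isinstance(feature_model, FeatureICAModel):
            g.attrs["kind"] = "ica"
            for name in (
                "channel_mean",
                "compression",
                "decompression",
                "unmixing",
                "mixing",
                "evoked_template",
                "component_templates",
            ):
                g.create_dataset(name, data=getattr(feature_model, name))
        elif isinstance(feature_model, PCABasis):
            g.attrs["kind"] = "st_pca"
            for name in ("eigenvectors", "eigenvalues", "mean"):
                g.create_dataset(name, data=getattr(feature_model, name))
        else:
            raise TypeError(f"unsupported feature model {type(feature_model).__name__}")
        g.attrs["window"] = [feature_model.window.start_ms, feature_model.window.end_ms]
        g.attrs["fs"] = feature_model.fs
        g.create_dataset("channels", data=np.array(feature_model.channel_names, dtype="S"))

        c = f.create_group("classifier")
        c.create_dataset("weights", data=classifier.weights)
        c.create_dataset("cv_curve", data=classifier.cv_curve)
        c.create_dataset("scaler_mean", data=classifier.scaler_mean)
        c.create_dataset("scaler_scale", data=classifier.scaler_scale)
        for attr in ("intercept", "penalty", "lam", "cv_accuracy", "feature_backend", "learner"):
            c.attrs[attr] = getattr(classifier, attr)
        c.attrs["metadata"] = json.dumps(classifier.metadata)
        f.attrs["config"] = json.dumps(config.to_dict())


def load_model(path):
    """Inverse of :func:`save_model`; fails on version mismatch."""
    from premove.features import FeatureICAModel, PCABasis

    with h5py.File(path, "r") as f:
        if int(f.attrs.get("format_version", -1)) != FORMAT_VERSION:
            raise ValueError(
                f"model format version {f.attrs.get('format_version')} "
                f"does not match supported version {FORMAT_VERSION}"
            )
        g = f["feature"]
        window = WindowSpec(*g.attrs["window"])
        channels = [ch.decode() for ch in g["channels"][()]]
        if g.attrs["kind"] == "ica":
            fmodel = FeatureICAModel(
                channel_mean=g["channel_mean"][()],
                compression=g["compression"][()],
                decompression=g["decompression"][()],
                unmixing=g["unmixing"][()],
                mixing=g["mixing"][()],
                evoked_template=g["evoked_template"][()],
                component_templates=g["component_templates"][()],
                window=window,
                channel_names=channels,
                fs=float(g.attrs["fs"]),
            )
        else:
            fmodel = PCABasis(
                eigenvectors=g["eigenvectors"][()],
                eigenvalues=g["eigenvalues"][()],
                mean=g["mean"][()],
                window=window,
                channel_names=channels,
                fs=float(g.attrs["fs"]),
            )
        c = f["classifier"]
        clf = ClassifierModel(
            weights=c["weights"][()],
            intercept=float(c.attrs["intercept"]),
            penalty=str(c.attrs["penalty"]),
            lam=float(c.attrs["lam"]),
            cv_curve=c["cv_curve"][()],
            cv_accuracy=float(c.attrs["cv_accuracy"]),
            scaler_mean=c["scaler_mean"][()],
            scaler_scale=c["scaler_scale"][()],
            feature_backend=str(c.attrs["feature_backend"]),
            learner=str(c.attrs["learner"]),
            metadata=json.loads(c.attrs["metadata"]),
        )
        config = PipelineConfig.from_dict(json.loads(f.attrs["config"]))
    return fmodel, clf, config
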