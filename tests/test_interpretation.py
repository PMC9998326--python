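"""Classifier topography, time-frequency contrast, minimum-norm inversion."""

import numpy as np
import pytest

from premove.classification import fit_logistic_cv
from premove.containers import EpochSet
from premove.features import FeatureICAModel, WindowSpec, fit_feature_ica, ica_features
from premove.interpretation import (
    Topography,
    classifier_topography,
    hemisphere_of,
    minimum_norm,
    tf_difference,
)
from premove.synthetic_data import Leadfield, make_leadfield

from conftest import make_noise_epochs


class TestHemisphereParsing:
    @pytest.mark.parametrize(
        "label,side",
        [("C1", "left"), ("C2", "right"), ("FCC3h", "left"), ("CCP4h", "right"),
         ("Cz", "midline"), ("AFp1", "left"), ("POz", "midline")],
    )
    def test_10_5_labels(self, label, side):
        assert hemisphere_of(label) == side


def _manual_model(mixing_col, channel_names, window=WindowSpec(-100, 100), t=51):
    m = len(mixing_col)
    return FeatureICAModel(
        channel_mean=np.zeros(len(channel_names)),
        compression=np.ones((1, len(channel_names))) / len(channel_names),
        decompression=np.asarray(mixing_col, dtype=float).reshape(-1, 1),
        unmixing=np.eye(1),
        mixing=np.eye(1),
        evoked_template=np.zeros((1, t)),
        component_templates=np.zeros((1, t)),
        window=window,
        channel_names=channel_names,
        fs=250.0,
    )


class TestClassifierTopography:
    def test_single_component_returns_its_mixing_column(self):
        from premove.classification import ClassifierModel

        col = np.array([1.0, -2.0, 0.5, 3.0])
        names = ["C1", "C2", "C3", "C4"]
        model = _manual_model(col, names)
        clf = ClassifierModel(
            weights=np.array([1.0, 0.0]),
            intercept=0.0,
            penalty="l1",
            lam=0.1,
            cv_curve=np.zeros((1, 2)),
            cv_accuracy=1.0,
            scaler_mean=np.zeros(2),
            scaler_scale=np.ones(2),
            feature_backend="ica",
        )
        topo = classifier_topography(model, clf)
        ratio = topo.values / col
        assert np.allclose(ratio, ratio[0])

    def test_sign_convention_left_hemisphere_positive(self):
        from premove.classification import ClassifierModel

        col = np.array([-5.0, 1.0])  # C1 (left) strongly negative
        model = _manual_model(col, ["C1", "C2"])
        clf = ClassifierModel(
            weights=np.array([1.0, 0.0]), intercept=0.0, penalty="l1", lam=0.1,
            cv_curve=np.zeros((1, 2)), cv_accuracy=1.0,
            scaler_mean=np.zeros(2), scaler_scale=np.ones(2), feature_backend="ica",
        )
        topo = classifier_topography(model, clf)
        assert topo.values[0] > 0  # flipped so the left peak is positive

    def test_planted_source_recovered_from_trained_decoder(self):
        rng = np.random.default_rng(0)
        n, c, t = 160, 8, 76
        times = (np.arange(t) - t // 2) / 250 * 1000
        pattern = np.array([3.0, -1.0, 2.0, 0.5, -2.0, 1.0, 0.0, -0.5])
        labels = np.array(["L", "R"] * (n // 2))
        signs = np.where(labels == "R", 1.0, -1.0)
        data = rng.standard_normal((n, c, t))
        data += signs[:, None, None] * 1.2 * pattern[None, :, None]
        ep = EpochSet(
            data=data, times=times, fs=250.0,
            channel_names=[f"C{i + 1}" for i in range(c)], labels=labels,
        )
        win = WindowSpec(times[2], times[-3])
        fmodel = fit_feature_ica(ep, win, m=6, seed=0)
        clf = fit_logistic_cv(ica_features(ep, fmodel), labels, seed=0, n_lambdas=10)
        topo = classifier_topography(fmodel, clf)
        assert abs(topo.correlation(pattern)) >= 0.9

    def test_feature_scaling_leaves_topography_invariant(self):
        rng = np.random.default_rng(1)
        n, c, t = 120, 6, 60
        times = (np.arange(t) - t // 2) / 250 * 1000
        pattern = np.array([2.0, -1.0, 1.5, -0.5, 1.0, 0.0])
        labels = np.array(["L", "R"] * (n // 2))
        signs = np.where(labels == "R", 1.0, -1.0)
        data = rng.standard_normal((n, c, t)) + signs[:, None, None] * pattern[None, :, None]
        ep = EpochSet(
            data=data, times=times, fs=250.0,
            channel_names=[f"C{i + 1}" for i in range(c)], labels=labels,
        )
        win = WindowSpec(times[2], times[-3])
        fmodel = fit_feature_ica(ep, win, m=4, seed=0)
        feats = ica_features(ep, fmodel)
        clf1 = fit_logistic_cv(feats, labels, seed=0, n_lambdas=10)
        scaled = type(feats)(values=feats.values * 10.0, descriptors=feats.descriptors,
                             backend=feats.backend)
        clf2 = fit_logistic_cv(scaled, labels, seed=0, n_lambdas=10)
        t1 = classifier_topography(fmodel, clf1).values
        # undo the raw-scale mismatch: clf2 saw features x10, so its
        # unstandardized weights shrink by 10; topography shape must match
        t2 = classifier_topography(fmodel, clf2).values * 10.0
        cos = abs(t1 @ t2) / (np.linalg.norm(t1) * np.linalg.norm(t2))
        assert cos > 0.999


def _osc_epochs(amp, freq=20.0, n=30, fs=250.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(-int(fs), int(fs) + 1) / fs  # +-1 s
    phases = rng.uniform(0, 2 * np.pi, n)
    data = amp * np.sin(2 * np.pi * freq * t[None, None, :] + phases[:, None, None])
    data = np.repeat(data, 2, axis=1) + 0.01 * rng.standard_normal((n, 2, len(t)))
    return EpochSet(
        data=data, times=t * 1000, fs=fs, channel_names=["C1", "C2"],
        labels=np.array(["R"] * n),
    )


class TestTFDifference:
    def test_identical_classes_give_zero_map(self):
        ep = _osc_epochs(1.0, seed=1)
        tf = tf_difference(ep, ep, ["C1"], f_lo=5, f_hi=40, t_window=(-150, 150))
        assert np.nanmax(np.abs(tf.values)) < 1e-12

    def test_antisymmetric_under_class_swap(self):
        a = _osc_epochs(1.0, seed=2)
        b = _osc_epochs(1.5, seed=3)
        tf_ab = tf_difference(a, b, ["C1", "C2"])
        tf_ba = tf_difference(b, a, ["C1", "C2"])
        assert np.allclose(tf_ab.values, -tf_ba.values, equal_nan=True)

    def test_two_to_one_power_ratio_maps_to_one_third(self):
        base = _osc_epochs(1.0, seed=4)
        doubled = base.copy()
        doubled.data = base.data * np.sqrt(2.0)  # doubled power
        tf = tf_difference(doubled, base, ["C1"], f_lo=10, f_hi=30)
        i20 = int(np.argmin(np.abs(tf.freqs - 20.0)))
        assert abs(np.nanmean(tf.values[i20]) - 1.0 / 3.0) < 0.02

    def test_values_bounded(self):
        a = _osc_epochs(1.0, seed=5)
        b = _osc_epochs(0.5, seed=6)
        tf = tf_difference(a, b, ["C1", "C2"])
        assert np.nanmax(np.abs(tf.values)) <= 1.0 + 1e-12

    def test_frequency_above_nyquist_rejected(self):
        ep = _osc_epochs(1.0, seed=7)
        with pytest.raises(ValueError):
            tf_difference(ep, ep, ["C1"], f_hi=200.0)


class TestMinimumNorm:
    def test_matches_pseudoinverse_least_norm_oracle(self):
        rng = np.random.default_rng(0)
        gain = rng.standard_normal((4, 3, 3))
        lf = Leadfield(gain=gain, source_positions=rng.standard_normal((3, 3)),
                       channel_names=["a", "b", "c", "d"])
        nu = rng.standard_normal(4)
        est = minimum_norm(nu, lf, reg=1e-16)
        oracle = np.linalg.pinv(gain.reshape(4, 9)) @ nu
        assert np.max(np.abs(est.coefficients.ravel() - oracle)) < 1e-8

    def test_zero_topography_gives_zero_estimate(self):
        lf = make_leadfield(8, 5, seed=1)
        est = minimum_norm(np.zeros(8), lf)
        assert np.allclose(est.amplitudes, 0.0)

    def test_linearity_in_topography(self):
        rng = np.random.default_rng(2)
        lf = make_leadfield(8, 5, seed=2)
        nu1, nu2 = rng.standard_normal(8), rng.standard_normal(8)
        c1 = minimum_norm(nu1, lf).coefficients
        c2 = minimum_norm(nu2, lf).coefficients
        c12 = minimum_norm(2 * nu1 + 3 * nu2, lf).coefficients
        assert np.allclose(c12, 2 * c1 + 3 * c2, atol=1e-8)

    def test_single_source_forward_field_localized(self):
        lf = make_leadfield(24, 6, seed=3)
        q = np.array([1.0, 0.5, -0.3])
        nu = lf.gain[:, 2, :] @ q
        est = minimum_norm(nu, lf)
        assert est.peak_source == 2

    def test_singular_unregularized_system_rejected(self):
        rng = np.random.default_rng(4)
        gain = np.zeros((4, 1, 3))
        gain[:, 0, 0] = rng.standard_normal(4)  # rank-1 forward model
        gain[:, 0, 1] = gain[:, 0, 0]
        gain[:, 0, 2] = gain[:, 0, 0]
        lf = Leadfield(gain=gain, source_positions=np.zeros((1, 3)),
                       channel_names=list("abcd"))
        with pytest.raises(np.linalg.LinAlgError):
            minimum_norm(rng.standard_normal(4), lf, reg=0.0)

    def test_channel_mismatch_rejected(self):
        lf = make_leadfield(8, 4, seed=5)
        topo = Topography(values=np.ones(5), channel_names=list("abcde"))
        with pytest.raises(ValueError):
            minimum_norm(topo, lf)
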