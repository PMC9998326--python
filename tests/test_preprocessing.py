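"""Filtering, epoching, rejection, referencing, cleaning ICA, EMG onsets."""

import numpy as np
import pytest

from premove.containers import EpochSet, Recording
from premove.preprocessing import (
    baseline_correct,
    clean_ica,
    detect_movement_onset,
    extract_epochs,
    fir_filter,
    reject_outliers,
    rereference,
    resample_epochs,
)

from conftest import make_noise_epochs


def _sine_recording(freq, fs=1000.0, dur=10.0, n_events=0):
    t = np.arange(int(dur * fs)) / fs
    data = np.sin(2 * np.pi * freq * t)[None, :].repeat(2, axis=0)
    events = np.linspace(3.0, dur - 3.0, n_events) if n_events else np.array([])
    return Recording(
        data=data,
        fs=fs,
        channel_names=["a", "b"],
        events=events,
        labels=np.array(["L"] * n_events),
    )


class TestFirFilter:
    def test_highpass_removes_dc(self):
        rec = _sine_recording(5.0)
        rec.data[:] = 1.0
        out = fir_filter(rec, "highpass", 1.0, order=1000)
        core = out.data[:, 2000:-2000]
        assert np.max(np.abs(core)) < 1e-6

    def test_lowpass_attenuates_60hz(self):
        rec = _sine_recording(60.0)
        out = fir_filter(rec, "lowpass", 45.0, order=500)
        core = out.data[0, 2000:-2000]
        assert np.sqrt(np.mean(core**2)) < 0.05 * np.sqrt(0.5)

    def test_bandpass_chain_preserves_10hz(self):
        rec = _sine_recording(10.0)
        out = fir_filter(fir_filter(rec, "highpass", 1.0, order=1000), "lowpass", 45.0, order=500)
        core = out.data[0, 3000:-3000]
        ref = rec.data[0, 3000:-3000]
        assert abs(np.sqrt(np.mean(core**2)) / np.sqrt(np.mean(ref**2)) - 1) < 0.02

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_filter(_sine_recording(5.0), "lowpass", 600.0, order=100)

    def test_length_preserved_on_epochs(self):
        ep = make_noise_epochs(n_trials=4)
        out = fir_filter(ep, "lowpass", 45.0, order=50)
        assert out.data.shape == ep.data.shape


class TestExtractEpochs:
    def test_shape_and_time_axis(self):
        rec = _sine_recording(5.0, fs=250.0, dur=40.0, n_events=10)
        ep = extract_epochs(rec, 2.5, 2.5)
        assert ep.data.shape == (10, 2, 1251)
        assert 0.0 in ep.times
        assert ep.times[0] == -2500.0

    def test_impulse_lands_at_t0(self):
        rec = _sine_recording(5.0, fs=250.0, dur=20.0, n_events=3)
        rec.data[:] = 0.0
        for t0 in rec.events:
            rec.data[:, int(round(t0 * rec.fs))] = 7.0
        ep = extract_epochs(rec, 1.0, 1.0)
        i0 = np.argmin(np.abs(ep.times))
        assert np.all(ep.data[:, :, i0] == 7.0)

    def test_edge_events_dropped_with_warning(self):
        rec = _sine_recording(5.0, fs=250.0, dur=20.0, n_events=3)
        rec.events[0] = 1.0  # less than 2.5 s from the start
        with pytest.warns(UserWarning, match="dropped"):
            ep = extract_epochs(rec, 2.5, 2.5)
        assert ep.n_trials == 2


class TestResample:
    def test_sine_resampled_accurately(self):
        fs = 5000.0
        t = np.arange(-12500, 12501) / fs
        data = np.sin(2 * np.pi * 2.0 * t)[None, None, :]
        ep = EpochSet(
            data=data,
            times=t * 1000,
            fs=fs,
            channel_names=["a"],
            labels=np.array(["L"]),
        )
        out = resample_epochs(ep, 1000.0)
        assert out.data.shape[2] == 5001
        expected = np.sin(2 * np.pi * 2.0 * out.times / 1000.0)
        core = slice(100, -100)
        assert np.max(np.abs(out.data[0, 0, core] - expected[core])) < 0.01
        assert np.any(out.times == 0.0)

    def test_identity_when_rate_matches(self):
        ep = make_noise_epochs(n_trials=3)
        out = resample_epochs(ep, ep.fs)
        assert np.array_equal(out.data, ep.data)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_epochs(make_noise_epochs(), 10_000.0)


class TestRejectOutliers:
    def test_planted_noisy_channel_removed(self):
        ep = make_noise_epochs(n_trials=30, n_channels=10, seed=3)
        ep.data[:, 4, :] *= 10.0  # 100x variance
        out, report = reject_outliers(ep, z_thresh=3.5)
        assert report.removed_channels == ["CH4"]
        assert out.n_channels == 9

    def test_clean_data_untouched_at_high_threshold(self):
        ep = make_noise_epochs(n_trials=30, n_channels=10, seed=4)
        out, report = reject_outliers(ep, z_thresh=10.0)
        assert report.removed_channels == [] and report.removed_trials == []
        assert out.data.shape == ep.data.shape

    def test_post_stimulus_artifact_ignored(self):
        ep = make_noise_epochs(n_trials=30, n_channels=10, seed=5)
        post = ep.times >= 0
        ep.data[:, 6, post] += 100.0  # huge artifact, but post-stimulus only
        _, report = reject_outliers(ep, z_thresh=3.5)
        assert "CH6" not in report.removed_channels

    def test_exclusion_list_always_removed(self):
        ep = make_noise_epochs(n_trials=20, n_channels=6, seed=6)
        out, report = reject_outliers(ep, z_thresh=10.0, exclude_channels=["CH0", "CH5"])
        assert report.excluded_channels == ["CH0", "CH5"]
        assert "CH0" not in out.channel_names


class TestRereference:
    def test_average_reference_zero_sum(self):
        ep = make_noise_epochs(n_trials=5, seed=7)
        out = rereference(ep, "average")
        assert np.max(np.abs(out.data.sum(axis=1))) < 1e-9 * np.abs(ep.data).max()

    def test_channel_reference_on_identical_channels_is_zero(self):
        ep = make_noise_epochs(n_trials=3, n_channels=4, seed=8)
        ep.data[:] = ep.data[:, :1, :]
        out = rereference(ep, "CH2")
        assert np.allclose(out.data, 0.0)
        assert "CH2" not in out.channel_names

    def test_average_reference_idempotent(self):
        ep = make_noise_epochs(n_trials=4, seed=9)
        once = rereference(ep, "average")
        twice = rereference(once, "average")
        assert np.allclose(once.data, twice.data)

    def test_missing_reference_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference(make_noise_epochs(), "Oz")


class TestCleanICA:
    def test_remove_nothing_is_identity_on_retained_subspace(self):
        ep = make_noise_epochs(n_trials=10, n_channels=6, seed=10)
        cleaned, model = clean_ica(ep, n_components=6, remove=[], seed=0)
        # full-rank compression: reconstruction error is numerical only
        assert np.allclose(cleaned.data, ep.data, atol=1e-8)

    def test_planted_blink_component_flagged(self, small_session):
        from premove.preprocessing import extract_epochs

        rec, truth = small_session
        ep = extract_epochs(rec)
        cleaned, model = clean_ica(ep, remove="auto_ocular", seed=0, fit_decim=4)
        assert model.removed_components, "no ocular component flagged"
        patterns = model.channel_patterns[:, model.removed_components]
        corr = np.max(
            [abs(np.corrcoef(p, truth.blink_topography)[0, 1]) for p in patterns.T]
        )
        assert corr > 0.9

    def test_removed_component_has_no_residual_time_course(self):
        ep = make_noise_epochs(n_trials=10, n_channels=6, seed=11)
        cleaned, model = clean_ica(ep, n_components=5, remove=[0, 2], seed=0)
        src = model.sources(cleaned.data)
        orig = model.sources(ep.data)
        for k in (0, 2):
            assert src[:, k].var() < 1e-6 * orig[:, k].var()

    def test_cleaning_decisions_causal(self):
        ep = make_noise_epochs(n_trials=12, n_channels=6, seed=12)
        _, model_a = clean_ica(ep, n_components=5, remove="auto_ocular", seed=0)
        perturbed = ep.copy()
        perturbed.data[:, :, perturbed.times >= 0] += 50.0
        _, model_b = clean_ica(perturbed, n_components=5, remove="auto_ocular", seed=0)
        assert np.array_equal(model_a.unmixing, model_b.unmixing)
        assert model_a.removed_components == model_b.removed_components


class TestBaseline:
    def test_pre_stimulus_mean_removed(self):
        ep = make_noise_epochs(n_trials=5, seed=13)
        ep.data += 11.0
        out = baseline_correct(ep)
        assert np.allclose(out.data[:, :, out.pre_mask].mean(axis=2), 0.0, atol=1e-12)


class TestMovementOnset:
    def _burst(self, fs, onset_s, dur_s=0.3, amp=50.0, total_s=1.5, seed=0):
        rng = np.random.default_rng(seed)
        x = 0.01 * rng.standard_normal(int(total_s * fs))
        i = int(onset_s * fs)
        n = int(dur_s * fs)
        x[i : i + n] += amp * rng.standard_normal(n)
        return x

    def test_burst_onset_recovered(self):
        fs = 1000.0
        emg = self._burst(fs, 0.3)
        onset = detect_movement_onset(emg, fs)
        assert abs(onset - 300.0) <= 15.0

    def test_flat_emg_returns_sentinel(self):
        assert np.isnan(detect_movement_onset(np.zeros(1000), 1000.0))

    def test_first_of_two_bursts_wins(self):
        fs = 1000.0
        emg = self._burst(fs, 0.3, amp=60.0) + self._burst(fs, 0.8, amp=40.0, seed=1)
        onset = detect_movement_onset(emg, fs)
        assert abs(onset - 300.0) <= 20.0
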