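"""The nine features: closed forms, spectral behaviour, batch path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magbehave as mb
from magbehave.core import ValidationError, Window
from magbehave.features import (
    FEATURE_NAMES,
    SpectrumConfig,
    avg_mean_abs_diff,
    ax_max_mean_abs_diff,
    compute_feature,
    extract_feature_matrix,
    mean_abs_diff_roll,
    mean_roll,
    periodicity_feature,
    power_spectrum,
    std_roll,
)


def make_window(samples, fs=100.0, label="foraging"):
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = np.column_stack([samples, samples, samples])
    return Window(samples=samples, label=label, session_id="s", individual_id="i",
                  start_time=0.0, fs=fs)


class TestScalarClosedForms:
    def test_mean_roll_of_constant(self):
        assert mean_roll(make_window(np.full(200, 5.0))) == pytest.approx(5.0)

    def test_std_roll_of_constant_is_zero(self):
        assert std_roll(make_window(np.full(200, 3.0))) == pytest.approx(0.0)

    def test_std_roll_alternating_uses_sample_convention(self):
        a, n = 2.5, 200
        x = a * (-1.0) ** np.arange(n)
        expected = a * np.sqrt(n / (n - 1))
        assert std_roll(make_window(x)) == pytest.approx(expected, rel=1e-12)

    def test_std_roll_of_unit_sine_is_rms(self):
        t = np.arange(200) / 100.0  # 4 full periods of 2 Hz in 2 s
        assert std_roll(make_window(np.sin(2 * np.pi * 2 * t))) == pytest.approx(
            1 / np.sqrt(2), rel=0.01)

    def test_mean_abs_diff_of_constant_is_zero(self):
        assert mean_abs_diff_roll(make_window(np.full(200, 9.0))) == 0.0

    def test_mean_abs_diff_of_ramp_is_slope(self):
        k, fs = 4.0, 100.0
        x = k * np.arange(200) / fs
        assert mean_abs_diff_roll(make_window(x, fs)) == pytest.approx(k, rel=1e-9)

    def test_mean_abs_diff_of_unit_2hz_sine_is_4af(self):
        fs, f = 100.0, 2.0
        t = np.arange(200) / fs
        win = make_window(np.sin(2 * np.pi * f * t), fs)
        # mean|cos| = 2/pi -> mean |d/dt| = 4*A*f, finite-difference oracle
        oracle = np.abs(np.diff(np.sin(2 * np.pi * f * t)) * fs).mean()
        value = mean_abs_diff_roll(win)
        assert value == pytest.approx(oracle, rel=1e-12)
        assert value == pytest.approx(8.0, rel=0.01)

    def test_axis_max_and_mean_on_distinct_ramps(self):
        fs = 100.0
        t = np.arange(200) / fs
        samples = np.column_stack([3 * t, 1 * t, 2 * t])
        win = make_window(samples, fs)
        assert ax_max_mean_abs_diff(win) == pytest.approx(3.0, rel=1e-9)
        assert avg_mean_abs_diff(win) == pytest.approx(2.0, rel=1e-9)

    def test_single_active_axis_mean(self):
        fs = 100.0
        t = np.arange(200) / fs
        samples = np.column_stack([3 * t, np.zeros(200), np.zeros(200)])
        assert avg_mean_abs_diff(make_window(samples, fs)) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_axis_mean_never_exceeds_axis_max(self, seed):
        rng = np.random.default_rng(seed)
        win = make_window(rng.normal(size=(60, 3)))
        assert avg_mean_abs_diff(win) <= ax_max_mean_abs_diff(win) + 1e-12


class TestPowerSpectrum:
    def test_pure_tone_located_within_grid_resolution(self):
        fs = 100.0
        t = np.arange(200) / fs
        for apply_lowpass in (True, False):
            ps = power_spectrum(np.sin(2 * np.pi * 3 * t), fs,
                                apply_lowpass=apply_lowpass)
            assert ps.peak_frequency() == pytest.approx(3.0, abs=0.01 + 1e-9)

    def test_constant_series_has_zero_spectrum(self):
        ps = power_spectrum(np.full(200, 5.0), 100.0)
        assert np.allclose(ps.power, 0.0)

    def test_two_tone_peak_at_dominant_component(self):
        fs = 100.0
        t = np.arange(200) / fs
        x = np.sin(2 * np.pi * 2 * t) + 0.3 * np.sin(2 * np.pi * 4 * t)
        ps = power_spectrum(x, fs)
        assert ps.peak_frequency() == pytest.approx(2.0, abs=0.01 + 1e-9)

    def test_grid_matches_configured_resolution(self, config):
        cfg = SpectrumConfig(resolution_hz=config.spectrum_resolution)
        ps = power_spectrum(np.random.default_rng(0).normal(size=200),
                            config.target_fs, cfg=cfg)
        assert ps.n_eval == cfg.n_freqs(config.target_fs)
        assert np.allclose(np.diff(ps.freqs), config.spectrum_resolution)
        assert ps.freqs.max() == pytest.approx(config.target_fs / 2)

    def test_non_integer_grid_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumConfig(resolution_hz=0.03).n_freqs(100.0)


class TestPeriodicityFeatures:
    def test_constant_window_gives_zero_for_all_variants(self):
        win = make_window(np.full(200, 2.0))
        for name in ("rollFftPeakPower", "avgFftPeakPower",
                     "rollDiffFftPeakPower", "avgDiffFftPeakPower"):
            assert compute_feature(win, name) == pytest.approx(0.0, abs=1e-18)

    def test_single_axis_tone_diluted_by_axis_averaging(self):
        rng = np.random.default_rng(3)
        fs = 100.0
        t = np.arange(200) / fs
        samples = np.column_stack([np.sin(2 * np.pi * 3 * t),
                                   rng.normal(0, 1, 200),
                                   rng.normal(0, 1, 200)])
        win = make_window(samples, fs)
        roll = periodicity_feature(win, "differentiated", "roll")
        avg = periodicity_feature(win, "differentiated", "triaxial")
        assert roll >= avg

    def test_unknown_variant_rejected(self):
        win = make_window(np.zeros(200))
        with pytest.raises(ValidationError):
            periodicity_feature(win, input="wavelet")


class TestScaleCovariance:
    def test_amplitude_features_scale_and_peaks_stay_put(self):
        rng = np.random.default_rng(8)
        fs = 100.0
        t = np.arange(200) / fs
        base = np.column_stack([np.sin(2 * np.pi * 3 * t) + 0.1 * rng.normal(size=200),
                                np.cos(2 * np.pi * 3 * t),
                                rng.normal(size=200)])
        a = 3.7
        w1, w2 = make_window(base, fs), make_window(a * base, fs)
        for name in ("meanRoll", "stdRoll", "meanAbsDiffRoll",
                     "axMaxMeanAbsDiff", "avgMeanAbsDiff"):
            assert compute_feature(w2, name) == pytest.approx(
                a * compute_feature(w1, name), rel=1e-9)
        ps1 = power_spectrum(base[:, 0], fs, apply_lowpass=False)
        ps2 = power_spectrum(a * base[:, 0], fs, apply_lowpass=False)
        assert ps1.peak_frequency() == ps2.peak_frequency()
        # normalisation makes peak power amplitude-invariant too
        assert ps1.peak_power() == pytest.approx(ps2.peak_power(), rel=1e-9)


class TestExtraction:
    def test_nine_features_no_missing_values(self):
        rng = np.random.default_rng(1)
        wins = [make_window(rng.normal(size=(200, 3))) for _ in range(7)]
        fm = extract_feature_matrix(wins)
        assert list(fm.columns[:9]) == list(FEATURE_NAMES)
        assert not fm[list(FEATURE_NAMES)].isna().any().any()

    def test_batch_path_matches_per_window_path(self):
        rng = np.random.default_rng(4)
        fs = 100.0
        t = np.arange(200) / fs
        wins = [make_window(np.column_stack([
            np.sin(2 * np.pi * 3 * t) + rng.normal(0, 0.3, 200),
            rng.normal(size=200), rng.normal(size=200)]), fs)
            for _ in range(5)]
        fm = extract_feature_matrix(wins)
        for i, win in enumerate(wins):
            for name in FEATURE_NAMES:
                assert fm.loc[i, name] == pytest.approx(
                    compute_feature(win, name), rel=1e-9), name

    def test_row_order_follows_window_order(self):
        rng = np.random.default_rng(5)
        wins = [make_window(rng.normal(size=(200, 3))) for _ in range(6)]
        fm = extract_feature_matrix(wins)
        perm = [3, 1, 5, 0, 2, 4]
        fm_perm = extract_feature_matrix([wins[i] for i in perm])
        expected = fm.iloc[perm].reset_index(drop=True)
        pd.testing.assert_frame_equal(fm_perm, expected)

    def test_unknown_feature_name_rejected(self):
        wins = [make_window(np.zeros((200, 3)))]
        with pytest.raises(ValidationError, match="unknown features"):
            extract_feature_matrix(wins, feature_names=("meanSurge",))

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValidationError):
            extract_feature_matrix([])


class TestStaticWindowArchetypes:
    def test_ideal_static_windows_have_flat_roll(self, field, still_profiles, config):
        from magbehave.pipeline import recordings_to_features
        recs = [
            mb.simulate_recording(field, [("vigilance", 10.0)],
                                  profiles=still_profiles, noise_sd=0.0, seed=0),
            mb.simulate_recording(field, [("resting", 10.0)],
                                  profiles=still_profiles, noise_sd=0.0, seed=0),
        ]
        fm = recordings_to_features(recs, config)
        # skip the first windows: the causal filter's startup transient
        fm = fm[fm.start_time >= 2.0]
        vig = fm[fm.label == "vigilance"]
        rest = fm[fm.label == "resting"]
        assert vig["meanRoll"].mean() == pytest.approx(field.vertical, rel=1e-3)
        assert rest["meanRoll"].mean() == pytest.approx(-field.vertical, rel=1e-3)
        assert vig["stdRoll"].max() < 1e-6
        assert vig["meanAbsDiffRoll"].max() < 1e-4
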