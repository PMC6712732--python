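"""Forward-model simulator: geometry, archetypes, determinism."""

import numpy as np
import pytest

import magbehave as mb
from magbehave.core import ValidationError
from magbehave.preprocessing import filter_recording, segment_windows, time_differentiate
from magbehave.simulate import (
    BehaviourProfile,
    IndividualParams,
    apply_sensor_distortion,
    orientation_to_samples,
    simulate_dataset,
    simulate_recording,
)


class TestFieldModel:
    def test_site_field_vertical_component(self):
        f = mb.make_earth_field(27.3, 65.0, 17.9)
        assert f.vertical == pytest.approx(27.3 * np.sin(np.radians(65.0)), abs=1e-9)
        assert f.vertical == pytest.approx(24.74, abs=5e-3)

    def test_zero_dip_is_purely_horizontal(self):
        f = mb.make_earth_field(1.0, 0.0, 0.0)
        assert f.vertical == pytest.approx(0.0, abs=1e-12)
        assert f.horizontal == pytest.approx(1.0)

    def test_vertical_field_has_no_horizontal_component(self):
        f = mb.make_earth_field(1.0, 90.0, 0.0)
        assert f.horizontal == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("magnitude,dip", [(0.0, 65.0), (-1.0, 65.0),
                                               (27.3, 95.0), (27.3, -91.0)])
    def test_invalid_parameters_rejected(self, magnitude, dip):
        with pytest.raises(ValidationError):
            mb.make_earth_field(magnitude, dip)


class TestStaticGeometry:
    def test_vigilance_roll_reads_plus_b_sin_dip(self, field, still_profiles):
        rec = simulate_recording(field, [("vigilance", 10.0)],
                                 profiles=still_profiles, noise_sd=0.0, seed=0)
        assert np.allclose(rec.samples[:, 0], field.vertical, atol=1e-9)

    def test_resting_roll_reads_minus_b_sin_dip(self, field, still_profiles):
        rec = simulate_recording(field, [("resting", 10.0)],
                                 profiles=still_profiles, noise_sd=0.0, seed=0)
        assert np.allclose(rec.samples[:, 0], -field.vertical, atol=1e-9)

    def test_noiseless_samples_lie_on_field_sphere(self, field):
        # rotation preserves length for every behaviour archetype
        rec = simulate_recording(
            field, [("vigilance", 3.0), ("resting", 3.0), ("foraging", 3.0),
                    ("running", 3.0)], noise_sd=0.0, seed=3)
        assert np.allclose(rec.norms(), field.magnitude, atol=1e-9)

    def test_horizontal_azimuth_sweep_spans_plus_minus_b_cos_dip(self, field):
        az = np.arange(0.0, 360.0, 0.5)
        zeros = np.zeros_like(az)
        samples = orientation_to_samples(zeros, az, zeros, field)
        roll = samples[:, 0]
        assert roll.max() == pytest.approx(field.horizontal, rel=1e-4)
        assert roll.min() == pytest.approx(-field.horizontal, rel=1e-4)


class TestRunningPeriodicity:
    def test_running_oscillation_peaks_at_stride_frequency(self, field):
        profiles = {"running": BehaviourProfile("running", 0.0, 0.0, 0.0,
                                                osc_freq=3.0, osc_amp=22.0)}
        rec = simulate_recording(field, [("running", 10.0)], profiles=profiles,
                                 noise_sd=0.0, seed=4, fs=100.0)
        rec = filter_recording(rec)
        win = segment_windows(rec)[3]
        ps = mb.power_spectrum(time_differentiate(win.roll, win.fs), win.fs,
                               apply_lowpass=False)
        assert ps.peak_frequency() == pytest.approx(3.0, abs=0.01 + 1e-9)


class TestScheduleAndDeterminism:
    def test_label_stream_matches_schedule(self, field):
        schedule = [("vigilance", 4.0), ("foraging", 6.0), ("running", 3.0)]
        rec = simulate_recording(field, schedule, seed=1)
        assert len(rec) == int(round(13.0 * rec.fs))
        for behaviour, duration in schedule:
            assert (rec.labels == behaviour).sum() == int(round(duration * rec.fs))
        assert "" not in set(rec.labels.tolist())

    def test_identical_seed_gives_identical_recording(self, field):
        kw = dict(schedule=[("foraging", 5.0), ("running", 3.0)], noise_sd=0.3)
        a = simulate_recording(field, seed=42, **kw)
        b = simulate_recording(field, seed=42, **kw)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.labels, b.labels)

    def test_unknown_behaviour_rejected(self, field):
        with pytest.raises(ValidationError, match="unknown behaviour"):
            simulate_recording(field, [("grooming", 5.0)])

    def test_supranyquist_stride_frequency_rejected(self, field):
        profiles = {"running": BehaviourProfile("running", 0.0, 5.0, 10.0,
                                                osc_freq=30.0, osc_amp=20.0)}
        with pytest.raises(ValidationError, match="Nyquist"):
            simulate_recording(field, [("running", 5.0)], profiles=profiles, fs=50.0)


class TestDataset:
    def test_every_recording_contains_at_least_three_behaviours(self):
        recs = simulate_dataset(4, 1, seed=9, session_minutes=8.0)
        assert len(recs) == 4
        for rec in recs:
            assert len(set(rec.labels.tolist())) >= 3

    def test_no_resting_sessions_config_is_honoured(self):
        skip = {2, 3}
        recs = simulate_dataset(4, 1, seed=9, session_minutes=8.0,
                                no_resting_sessions=skip)
        for i, rec in enumerate(recs, start=1):
            has_resting = (rec.labels == "resting").any()
            assert has_resting == (i not in skip)

    def test_same_seed_gives_identical_label_streams(self):
        a = simulate_dataset(3, 1, seed=7, session_minutes=5.0)
        b = simulate_dataset(3, 1, seed=7, session_minutes=5.0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.labels, rb.labels)
            assert np.array_equal(ra.samples, rb.samples)

    def test_study_design_structure(self):
        recs = mb.make_study_dataset(seed=2, session_minutes=5.0)
        assert len(recs) == 11
        # sessions 4 and 7 belong to the same individual
        by_session = {r.session_id: r for r in recs}
        assert by_session["sess04"].individual_id == by_session["sess07"].individual_id
        assert len({r.individual_id for r in recs}) == 10
        for s in (3, 4, 5, 8, 9, 10):
            assert not (by_session[f"sess{s:02d}"].labels == "resting").any()
        for s in (1, 2, 6, 11):
            assert (by_session[f"sess{s:02d}"].labels == "resting").any()


class TestSensorDistortion:
    def test_identity_distortion_is_a_no_op(self, field):
        rec = simulate_recording(field, [("foraging", 5.0)], seed=0)
        out = apply_sensor_distortion(rec, np.zeros(3), np.eye(3))
        assert np.array_equal(out.samples, rec.samples)

    def test_hard_iron_shifts_channel_means(self, field):
        rec = simulate_recording(field, [("foraging", 5.0)], seed=0)
        out = apply_sensor_distortion(rec, [5.0, 0.0, 0.0], np.eye(3))
        shift = out.samples.mean(axis=0) - rec.samples.mean(axis=0)
        assert shift == pytest.approx([5.0, 0.0, 0.0], abs=1e-12)

    def test_soft_iron_breaks_norm_constancy(self, field):
        rec = simulate_recording(field, [("foraging", 5.0)], noise_sd=0.0, seed=0)
        out = apply_sensor_distortion(rec, np.zeros(3), np.diag([2.0, 1.0, 1.0]))
        assert np.ptp(out.norms()) > 1.0  # sphere became an ellipsoid

    def test_singular_soft_iron_rejected(self, field):
        rec = simulate_recording(field, [("foraging", 5.0)], seed=0)
        singular = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValidationError, match="invertible"):
            apply_sensor_distortion(rec, np.zeros(3), singular)
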