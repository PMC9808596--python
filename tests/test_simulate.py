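"""Simulator determinism, validity, and degenerate-case behavior.

Statistical parameter-recovery checks (slope bias, clinical link, pulse
rate, step trend) live in the acceptance suite; here we pin the exact and
structural guarantees.
"""

import numpy as np
import pytest

from rehabsense.eda import segment_stats
from rehabsense.simulate import (
    CohortSpec,
    latent_movement_changes,
    simulate_activity,
    simulate_clinical,
    simulate_eda,
    simulate_motion,
)
from rehabsense.types import ARM_DTXP, SpecError
from rehabsense.velocity import classify_series, fit_daily_slope


def small_spec(**kw):
    defaults = dict(
        n_participants=3, n_sham=2, n_standard_care=2, n_study_days=5,
        action_segments_per_day=2, noaction_segments_per_day=2,
        segment_duration_s=1.0, sample_rate_motion=10.0, sensors=("head",),
        eda_days=2, eda_segments_per_day=3, eda_segment_duration_s=30.0, seed=11,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_participants": 1},
            {"action_segments_per_day": 0},
            {"segment_duration_s": 0.0},
            {"clinical_link_strength": 1.5},
            {"sensors": ("head", "knee")},
            {"n_study_days": 0},
        ],
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(SpecError):
            small_spec(**kw).validate()


class TestMotion:
    def test_fixed_seed_reproduces_identical_streams(self):
        a = simulate_motion(small_spec())
        b = simulate_motion(small_spec())
        for sa, sb in zip(a, b):
            for ga, gb in zip(sa.segments, sb.segments):
                np.testing.assert_array_equal(ga.t, gb.t)
                np.testing.assert_array_equal(ga.xyz, gb.xyz)

    def test_different_seeds_differ(self):
        a = simulate_motion(small_spec(seed=1))
        b = simulate_motion(small_spec(seed=2))
        assert not np.array_equal(a[0].segments[0].xyz, b[0].segments[0].xyz)

    def test_noise_free_slope_equals_injected_beta(self):
        spec = small_spec(
            improvement_slope_sd=0.0, segment_velocity_sd=0.0,
            within_segment_speed_cv=0.0, n_study_days=8,
        )
        for series in simulate_motion(spec):
            classify_series(series, {"task"})
            est = fit_daily_slope(series, "head")
            assert est.slope == pytest.approx(spec.improvement_slope_mean, abs=1e-9)

    def test_generated_segments_obey_data_model(self):
        for series in simulate_motion(small_spec()):
            assert series.arm == ARM_DTXP
            days = {s.study_day for s in series.segments}
            assert series.vr_study_day_count == len(days)
            for seg in series.segments:
                assert np.all(np.diff(seg.t) > 0)
                assert np.all(np.isfinite(seg.xyz))

    def test_action_segments_move_faster_with_beta_zero(self):
        spec = small_spec(
            improvement_slope_mean=0.0, improvement_slope_sd=0.0,
            segment_velocity_sd=0.0, within_segment_speed_cv=0.0,
            action_vs_noaction_velocity_ratio=2.0,
        )
        (series, *_) = simulate_motion(spec)
        classify_series(series, {"task"})
        from rehabsense.velocity import segment_velocities

        svs = segment_velocities(series)
        action = np.mean([s.mean_velocity for s in svs if s.action_class == "action"])
        noaction = np.mean([s.mean_velocity for s in svs if s.action_class != "action"])
        assert action / noaction == pytest.approx(2.0, rel=1e-9)


class TestClinical:
    def test_perfect_link_without_rounding(self):
        spec = small_spec(clinical_link_strength=1.0, n_participants=6)
        motion = simulate_motion(spec)
        clin = simulate_clinical(spec, motion, round_to_int=False)
        m = latent_movement_changes(spec, motion)
        vas = np.array([c.vas_chg for c in clin])
        tampa = np.array([c.tampa_chg for c in clin])
        assert abs(np.corrcoef(m, vas)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert np.corrcoef(m, tampa)[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_rounding_yields_integer_scales(self):
        spec = small_spec()
        motion = simulate_motion(spec)
        for c in simulate_clinical(spec, motion):
            assert float(c.tampa_chg).is_integer()
            assert float(c.vas_chg).is_integer()
            assert float(c.eq5d_chg).is_integer()

    def test_mismatched_participant_sets_rejected(self):
        spec = small_spec()
        motion = simulate_motion(spec)
        with pytest.raises(SpecError):
            simulate_clinical(spec.replace(n_participants=5), motion)

    def test_zero_link_near_zero_correlation(self):
        """rho = 0: movement and endpoints decouple.  At n = 50 the null
        sample correlation has sd ~ 1/sqrt(n-1) ~ 0.14, so |r| < 0.2 holds
        for ~84% of replicates and the mean correlation sits near 0."""
        hits = 0
        rs = []
        reps = 100
        for rep in range(reps):
            spec = CohortSpec(
                n_participants=50, n_study_days=10, action_segments_per_day=1,
                noaction_segments_per_day=0, segment_duration_s=0.2,
                sample_rate_motion=10.0, sensors=("head",),
                clinical_link_strength=0.0, seed=50_000 + rep,
            )
            motion = simulate_motion(spec)
            clin = simulate_clinical(spec, motion)
            m = latent_movement_changes(spec, motion)
            vas = np.array([c.vas_chg for c in clin])
            r = np.corrcoef(m, vas)[0, 1]
            rs.append(r)
            if abs(r) < 0.2:
                hits += 1
        assert hits / reps >= 0.7
        assert abs(np.mean(rs)) < 0.05


class TestEda:
    def test_fixed_seed_determinism(self):
        a = simulate_eda(small_spec())
        b = simulate_eda(small_spec())
        for sa, sb in zip(a, b):
            for ga, gb in zip(sa.segments, sb.segments):
                np.testing.assert_array_equal(ga.values, gb.values)

    def test_zero_rate_zero_noise_yields_zero_peaks(self):
        spec = small_spec(
            eda_pulse_rate=0.0, eda_pulse_rate_sham=0.0, eda_noise_sd=0.0,
            eda_tonic_amplitude=0.0,
        )
        for series in simulate_eda(spec):
            for st in segment_stats(series, drop_start_of_day=False):
                assert st.peak_count == 0

    def test_arm_sizes_and_labels(self):
        spec = small_spec()
        series = simulate_eda(spec)
        arms = [s.arm for s in series]
        assert arms.count("DTxP") == spec.n_participants
        assert arms.count("Sham") == spec.n_sham
        dtxp = next(s for s in series if s.arm == "DTxP")
        assert all(s.action_class is not None for s in dtxp.segments)
        sham = next(s for s in series if s.arm == "Sham")
        assert all(s.action_class is None for s in sham.segments)


class TestActivity:
    def test_zero_trend_zero_noise_constant_steps(self):
        spec = small_spec(
            weekly_step_trend={"DTxP": 0.0, "Sham": 0.0, "StandardCare": 0.0},
            step_noise_sd=0.0,
        )
        days = simulate_activity(spec)
        assert {d.steps for d in days} == {int(spec.steps_baseline)}

    def test_negative_draws_truncated_to_zero(self):
        spec = small_spec(steps_baseline=10.0, step_noise_sd=2000.0)
        days = simulate_activity(spec)
        assert min(d.steps for d in days) == 0
        assert all(d.steps >= 0 for d in days)

    def test_fixed_seed_determinism(self):
        assert simulate_activity(small_spec()) == simulate_activity(small_spec())
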