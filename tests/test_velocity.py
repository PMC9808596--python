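"""Velocity computation, segment context classification, and trend fits."""

import math

import numpy as np
import pytest

from rehabsense.types import (
    ACTION,
    DegenerateDesignError,
    InsufficientDataError,
    MotionSegment,
    NO_ACTION_BETWEEN,
    NO_ACTION_END_OF_DAY,
    NO_ACTION_START_OF_DAY,
    ParticipantMotionSeries,
)
from rehabsense.velocity import (
    classify_segment_context,
    fit_daily_slope,
    point_velocities,
    segment_mean_velocity,
    segment_velocities,
    velocity_by_class_summary,
)

from .conftest import make_segment, random_segment


def brute_force_velocities(segment, gap_threshold=0.5, cap=None):
    """Independent pairwise-difference oracle, plain Python."""
    out = []
    for i in range(1, segment.n_samples):
        dt = float(segment.t[i] - segment.t[i - 1])
        if dt <= 0 or dt > gap_threshold:
            continue
        dx, dy, dz = (float(a) - float(b) for a, b in zip(segment.xyz[i], segment.xyz[i - 1]))
        v = math.sqrt(dx * dx + dy * dy + dz * dz) / dt
        if cap is not None and v > cap:
            continue
        out.append(v)
    return np.array(out)


class TestPointVelocities:
    def test_hand_computed_3_4_5(self):
        # displacement (0.3, 0.4, 0) m over 0.1 s -> 0.5 m / 0.1 s = 5 m/s
        seg = make_segment([0.0, 0.1], [[0, 0, 0], [0.3, 0.4, 0.0]])
        pts = point_velocities(seg)
        assert pts.v.shape == (1,)
        assert pts.v[0] == pytest.approx(5.0, abs=1e-12)

    def test_stationary_sensor_gives_zero(self):
        seg = make_segment(np.arange(10) * 0.1, np.ones((10, 3)))
        assert np.all(point_velocities(seg).v == 0.0)

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(50):
            seg = random_segment(rng, n=100)
            np.testing.assert_array_equal(point_velocities(seg).v, brute_force_velocities(seg))

    def test_gap_pairs_skipped_and_counted(self):
        t = [0.0, 0.033, 2.0, 2.033]  # one 1.967 s recording gap
        seg = make_segment(t, np.arange(12).reshape(4, 3) * 0.001)
        pts = point_velocities(seg, gap_threshold=0.5)
        assert pts.n_gap_skipped == 1
        assert pts.v.size == 2

    def test_velocity_cap_drops_and_counts(self):
        seg = make_segment([0.0, 0.1, 0.2], [[0, 0, 0], [5, 0, 0], [5.01, 0, 0]])
        pts = point_velocities(seg, velocity_cap=10.0)
        assert pts.n_capped == 1
        assert pts.v.size == 1

    def test_single_sample_is_insufficient(self):
        seg = make_segment([0.0], [[0, 0, 0]])
        with pytest.raises(InsufficientDataError):
            point_velocities(seg)

    def test_translation_and_rotation_invariance(self, rng):
        """Speed is preserved by any rigid transform of the trajectory."""
        from scipy.spatial.transform import Rotation

        for _ in range(20):
            seg = random_segment(rng)
            v0 = point_velocities(seg).v
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=5.0, size=3)
            moved = make_segment(seg.t, seg.xyz @ rot.T + shift)
            np.testing.assert_allclose(point_velocities(moved).v, v0, rtol=0, atol=1e-9)

    def test_doubling_dt_halves_velocity(self, rng):
        seg = random_segment(rng)
        slow = make_segment(seg.t * 2.0, seg.xyz)
        np.testing.assert_allclose(
            point_velocities(slow, gap_threshold=1.0).v,
            point_velocities(seg).v / 2.0,
            rtol=1e-12,
        )


class TestSegmentMean:
    def test_mean_of_two_points(self):
        seg = make_segment([0.0, 0.1, 0.2], [[0, 0, 0], [0.1, 0, 0], [0.4, 0, 0]])
        sv = segment_mean_velocity(point_velocities(seg), seg)
        assert sv.mean_velocity == pytest.approx(2.0)
        assert sv.duration == pytest.approx(0.2)
        assert sv.n_points == 2

    def test_single_point_identity(self):
        seg = make_segment([0.0, 0.1], [[0, 0, 0], [0.3, 0.4, 0.0]])
        assert segment_mean_velocity(point_velocities(seg), seg).mean_velocity == 5.0

    def test_matches_fsum_oracle(self, rng):
        seg = random_segment(rng, n=1001)
        pts = point_velocities(seg)
        sv = segment_mean_velocity(pts, seg)
        expected = math.fsum(map(float, pts.v)) / pts.v.size
        assert sv.mean_velocity == pytest.approx(expected, rel=1e-12)


def classify_oracle(flags):
    """Brute-force index-scan oracle for context labels."""
    idx = [i for i, a in enumerate(flags) if a]
    if not idx:
        return [NO_ACTION_START_OF_DAY] * len(flags)
    out = []
    for i, a in enumerate(flags):
        if a:
            out.append(ACTION)
        elif i < min(idx):
            out.append(NO_ACTION_START_OF_DAY)
        elif i > max(idx):
            out.append(NO_ACTION_END_OF_DAY)
        else:
            out.append(NO_ACTION_BETWEEN)
    return out


class TestClassifyContext:
    def _segments(self, flags):
        return [
            make_segment(
                [0.0, 0.1],
                [[0, 0, 0], [0.1, 0, 0]],
                tag="task" if a else "idle",
                segment_id=f"s{i}",
            )
            for i, a in enumerate(flags)
        ]

    def test_canonical_day_layout(self):
        segs = classify_segment_context(self._segments([False, True, False, True, False]), {"task"})
        assert [s.action_class for s in segs] == [
            NO_ACTION_START_OF_DAY,
            ACTION,
            NO_ACTION_BETWEEN,
            ACTION,
            NO_ACTION_END_OF_DAY,
        ]

    def test_all_action_day(self):
        segs = classify_segment_context(self._segments([True, True]), {"task"})
        assert [s.action_class for s in segs] == [ACTION, ACTION]

    def test_no_action_day_warns_and_labels_start(self):
        with pytest.warns(UserWarning, match="zero action"):
            segs = classify_segment_context(self._segments([False, False]), {"task"})
        assert {s.action_class for s in segs} == {NO_ACTION_START_OF_DAY}

    def test_random_layouts_match_index_scan_oracle(self, rng):
        for _ in range(50):
            flags = list(rng.random(rng.integers(1, 12)) < 0.5)
            if not any(flags):
                continue
            segs = classify_segment_context(self._segments(flags), {"task"})
            assert [s.action_class for s in segs] == classify_oracle(flags)


def linear_series(slope, intercept=0.1, days=30, per_day=2, dt=0.1):
    """Segments whose mean velocity is exactly intercept + slope * day."""
    segments = []
    for d in range(1, days + 1):
        v = intercept + slope * d
        for k in range(per_day):
            t = np.arange(5) * dt
            xyz = np.zeros((5, 3))
            xyz[:, 0] = np.arange(5) * v * dt  # constant speed v
            segments.append(
                make_segment(t, xyz, study_day=d, segment_id=f"d{d}k{k}", tag="task",
                             action_class=ACTION)
            )
    return ParticipantMotionSeries("P1", "DTxP", segments)


class TestFitDailySlope:
    def test_exact_linear_input(self):
        est = fit_daily_slope(linear_series(0.003), "head")
        assert est.slope == pytest.approx(0.003, abs=1e-12)
        assert est.change == pytest.approx(0.003 * 30, abs=1e-12)
        assert est.vr_study_day_count == 30

    def test_constant_velocity_gives_zero_slope(self):
        est = fit_daily_slope(linear_series(0.0), "head")
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_change_equals_slope_times_days(self, rng):
        series = linear_series(0.002)
        est = fit_daily_slope(series, "head")
        assert est.change == est.slope * est.vr_study_day_count

    def test_matches_closed_form_ols_oracle(self, rng):
        series = linear_series(0.001)
        # perturb each segment's speed via fresh random trajectories
        segments = []
        for i, d in enumerate(rng.integers(1, 20, size=40)):
            segments.append(
                random_segment(rng, n=30, study_day=int(d), segment_id=f"r{i}",
                               tag="task")
            )
        for s in segments:
            s.action_class = ACTION
        series = ParticipantMotionSeries("P1", "DTxP", segments)
        est = fit_daily_slope(series, "head")
        svs = [sv for sv in segment_velocities(series) if sv.action_class == ACTION]
        d = np.array([sv.study_day for sv in svs], float)
        v = np.array([sv.mean_velocity for sv in svs])
        oracle = np.sum((d - d.mean()) * (v - v.mean())) / np.sum((d - d.mean()) ** 2)
        assert est.slope == pytest.approx(oracle, abs=1e-10)

    def test_single_day_design_is_degenerate(self):
        series = linear_series(0.003, days=1, per_day=4)
        with pytest.raises(DegenerateDesignError):
            fit_daily_slope(series, "head")

    def test_too_few_action_segments(self):
        series = linear_series(0.003, days=1, per_day=1)
        with pytest.raises(InsufficientDataError):
            fit_daily_slope(series, "head")


class TestClassSummary:
    def test_counts_sum_to_total_segments(self, rng):
        segs = [
            random_segment(rng, n=20, segment_id=f"s{i}", tag="task" if i % 2 else "idle")
            for i in range(10)
        ]
        classify_segment_context(segs, {"task"})
        series = ParticipantMotionSeries("P1", "DTxP", segs)
        summary = velocity_by_class_summary(series)
        assert summary["count"].sum() == 10

    def test_absent_class_reported_empty(self, rng):
        segs = [random_segment(rng, n=20, segment_id=f"s{i}", tag="task") for i in range(4)]
        classify_segment_context(segs, {"task"})
        series = ParticipantMotionSeries("P1", "DTxP", segs)
        summary = velocity_by_class_summary(series)
        action_row = summary[summary.action_class == ACTION].iloc[0]
        assert action_row["count"] == 4
        other = summary[summary.action_class != ACTION]
        assert (other["count"] == 0).all()
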