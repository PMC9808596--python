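"""Movement-velocity biomarker: per-point speeds, segment averages, and
per-participant change estimates.

The core quantity is the instantaneous speed between consecutive position
samples,

    v = sqrt(dx^2 + dy^2 + dz^2) / dt,

averaged per metadata-tagged segment.  A participant's progress over the
study is summarized by an ordinary least-squares fit of action-segment mean
velocity on the VR study-day ordinal; the slope (m/s per day) times the
participant's count of VR study days gives the velocity change over the
study, the quantity correlated with clinical endpoint changes downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ACTION,
    NO_ACTION_BETWEEN,
    NO_ACTION_END_OF_DAY,
    NO_ACTION_START_OF_DAY,
    ChangeEstimate,
    DegenerateDesignError,
    InsufficientDataError,
    MotionSegment,
    ParticipantMotionSeries,
)

#: Largest plausible sample spacing (s); consecutive pairs further apart are
#: treated as recording gaps, not movement.  Nominal spacing is ~0.033 s.
DEFAULT_GAP_THRESHOLD = 0.5


@dataclass
class PointVelocities:
    """Per-timepoint speeds of one segment.

    ``t`` carries the later timestamp of each sample pair.  ``n_gap_skipped``
    counts pairs dropped for non-positive or over-threshold dt;
    ``n_capped`` counts points dropped by the optional speed cap (guards
    against non-natural movement such as a dropped controller).
    """

    t: np.ndarray
    v: np.ndarray
    n_gap_skipped: int = 0
    n_capped: int = 0


@dataclass
class SegmentVelocity:
    """Average speed of one segment (the unit of downstream analysis)."""

    segment_id: str
    sensor: str
    study_day: int
    action_class: str | None
    mean_velocity: float
    duration: float
    n_points: int


def point_velocities(
    segment: MotionSegment,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    velocity_cap: float | None = None,
) -> PointVelocities:
    """Compute per-timepoint speeds from consecutive sample pairs.

    Pairs with ``dt <= 0`` or ``dt > gap_threshold`` are skipped and
    counted; if ``velocity_cap`` is set, speeds above it are dropped and
    counted.  The first sample yields no point.

    Raises :class:`InsufficientDataError` when fewer than two samples are
    available or no usable pair remains; callers exclude the segment rather
    than abort.
    """
    if segment.n_samples < 2:
        raise InsufficientDataError(
            f"segment {segment.segment_id}: {segment.n_samples} samples, need >= 2"
        )
    dt = np.diff(segment.t)
    disp = np.linalg.norm(np.diff(segment.xyz, axis=0), axis=1)
    usable = (dt > 0) & (dt <= gap_threshold)
    n_gap = int(np.sum(~usable))
    t = segment.t[1:][usable]
    v = disp[usable] / dt[usable]
    n_capped = 0
    if velocity_cap is not None:
        over = v > velocity_cap
        n_capped = int(over.sum())
        t, v = t[~over], v[~over]
    if v.size == 0:
        raise InsufficientDataError(
            f"segment {segment.segment_id}: no usable sample pair"
        )
    return PointVelocities(t=t, v=v, n_gap_skipped=n_gap, n_capped=n_capped)


def segment_mean_velocity(
    points: PointVelocities, segment: MotionSegment
) -> SegmentVelocity:
    """Aggregate point speeds to the segment's average velocity."""
    if points.v.size == 0:
        raise InsufficientDataError(f"segment {segment.segment_id}: no velocity points")
    return SegmentVelocity(
        segment_id=segment.segment_id,
        sensor=segment.sensor,
        study_day=segment.study_day,
        action_class=segment.action_class,
        mean_velocity=float(np.mean(points.v)),
        duration=float(segment.t[-1] - segment.t[0]),
        n_points=int(points.v.size),
    )


def classify_segment_context(
    segments: list[MotionSegment], action_tags: set[str]
) -> list[MotionSegment]:
    """Assign action classes to one participant-day's ordered segments.

    Segments whose tag is in ``action_tags`` become ``action``.  No-action
    segments before the day's first action segment are ``start of day``,
    after the last one ``end of day``, otherwise ``between``.  A day with no
    action segment labels everything start-of-day and warns.

    Mutates and returns the same list (classification is metadata).  Tags
    may carry a sequence suffix after a colon (``task:7``); the map is
    checked against both the full tag and its base before the colon.
    """
    is_action = [
        s.tag in action_tags or s.tag.split(":")[0] in action_tags for s in segments
    ]
    action_idx = [i for i, a in enumerate(is_action) if a]
    if not action_idx:
        warnings.warn(
            "day has zero action segments; labeling all no-action as start of day",
            stacklevel=2,
        )
        for s in segments:
            s.action_class = NO_ACTION_START_OF_DAY
        return segments
    first, last = action_idx[0], action_idx[-1]
    for i, s in enumerate(segments):
        if is_action[i]:
            s.action_class = ACTION
        elif i < first:
            s.action_class = NO_ACTION_START_OF_DAY
        elif i > last:
            s.action_class = NO_ACTION_END_OF_DAY
        else:
            s.action_class = NO_ACTION_BETWEEN
    return segments


def classify_series(
    series: ParticipantMotionSeries, action_tags: set[str]
) -> ParticipantMotionSeries:
    """Classify every (sensor, study-day) group of a participant's segments."""
    groups: dict[tuple[str, int], list[MotionSegment]] = {}
    for seg in series.segments:
        groups.setdefault((seg.sensor, seg.study_day), []).append(seg)
    for group in groups.values():
        classify_segment_context(group, action_tags)
    return series


def segment_velocities(
    series: ParticipantMotionSeries,
    sensor: str | None = None,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    velocity_cap: float | None = None,
) -> list[SegmentVelocity]:
    """Per-segment average velocities, skipping unusable segments."""
    out = []
    for seg in series.segments:
        if sensor is not None and seg.sensor != sensor:
            continue
        try:
            pts = point_velocities(seg, gap_threshold, velocity_cap)
        except InsufficientDataError:
            continue
        out.append(segment_mean_velocity(pts, seg))
    return out


def fit_daily_slope(
    series: ParticipantMotionSeries,
    sensor: str,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    velocity_cap: float | None = None,
) -> ChangeEstimate:
    """OLS trend of action-segment mean velocity over VR study days.

    One observation per action segment, located at its 1-based study-day
    ordinal (not calendar time: study days may span multiple calendar days,
    so the fit is a proxy for progression, not a rate per calendar day).
    The change estimate is slope times the participant's VR study-day count.
    """
    segvels = [
        sv
        for sv in segment_velocities(series, sensor, gap_threshold, velocity_cap)
        if sv.action_class == ACTION
    ]
    if len(segvels) < 2:
        raise InsufficientDataError(
            f"participant {series.participant_id}/{sensor}: "
            f"{len(segvels)} action segments, need >= 2"
        )
    days = np.array([sv.study_day for sv in segvels], dtype=float)
    vels = np.array([sv.mean_velocity for sv in segvels])
    if np.unique(days).size < 2:
        raise DegenerateDesignError(
            f"participant {series.participant_id}/{sensor}: all action segments "
            "on one study day"
        )
    slope = float(np.polyfit(days, vels, 1)[0])
    n_days = series.vr_study_day_count
    return ChangeEstimate(
        participant_id=series.participant_id,
        sensor=sensor,
        slope=slope,
        change=slope * n_days,
        n_segments=len(segvels),
        vr_study_day_count=n_days,
    )


def velocity_by_class_summary(
    series: ParticipantMotionSeries,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    velocity_cap: float | None = None,
) -> pd.DataFrame:
    """Distribution of segment mean velocities per sensor and action class.

    The segmentation validity check: action segments should show faster
    average movement than no-action segments.  Returns one row per
    (sensor, action_class) with count, mean and quartiles; classes absent
    for a sensor are reported with count 0.
    """
    segvels = segment_velocities(series, None, gap_threshold, velocity_cap)
    df = pd.DataFrame(
        {
            "sensor": [sv.sensor for sv in segvels],
            "action_class": [sv.action_class for sv in segvels],
            "mean_velocity": [sv.mean_velocity for sv in segvels],
        }
    )
    rows = []
    classes = sorted({sv.action_class for sv in segvels} | {ACTION})
    for sensor_name in sorted({sv.sensor for sv in segvels}):
        for cls in classes:
            sel = df[(df.sensor == sensor_name) & (df.action_class == cls)]
            v = sel["mean_velocity"]
            rows.append(
                {
                    "sensor": sensor_name,
                    "action_class": cls,
                    "count": len(sel),
                    "mean": v.mean() if len(sel) else np.nan,
                    "q25": v.quantile(0.25) if len(sel) else np.nan,
                    "median": v.median() if len(sel) else np.nan,
                    "q75": v.quantile(0.75) if len(sel) else np.nan,
                }
            )
    return pd.DataFrame(rows)
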