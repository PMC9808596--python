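"""Shared domain types for the wearable-sensor analysis pipeline.

The pipeline handles four data streams collected around a VR rehabilitation
program for chronic low back pain:

* tri-axial position streams (~30 Hz) from a head-mounted display and two
  hand controllers, segmented by the VR software's metadata tags;
* electrodermal activity (skin conductance, 4 Hz) from a wrist wearable;
* daily activity aggregates (steps, heart rate, sleep);
* clinical endpoint changes (Tampa Scale of Kinesiophobia, EQ-5D overall
  health VAS, EQ-5D-5L index), end of treatment minus baseline.

Motion and EDA segments store their samples as numpy arrays for speed; the
dataclasses carry the identifying metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

# Trial arms
ARM_DTXP = "DTxP"
ARM_SHAM = "Sham"
ARM_STANDARD_CARE = "StandardCare"
ARMS = (ARM_DTXP, ARM_SHAM, ARM_STANDARD_CARE)

# Sensor labels
SENSOR_HEAD = "head"
SENSOR_LEFT = "left"
SENSOR_RIGHT = "right"
SENSORS = (SENSOR_HEAD, SENSOR_LEFT, SENSOR_RIGHT)

# Segment action classes.  A segment is either "action" (a VR task was
# active) or no-action; no-action segments are sub-classified by their
# position relative to the day's action segments.
ACTION = "action"
NO_ACTION_START_OF_DAY = "no_action_start_of_day"
NO_ACTION_BETWEEN = "no_action_between"
NO_ACTION_END_OF_DAY = "no_action_end_of_day"
ACTION_CLASSES = (
    ACTION,
    NO_ACTION_START_OF_DAY,
    NO_ACTION_BETWEEN,
    NO_ACTION_END_OF_DAY,
)

#: Column order of a cohort change table (one row per participant).
CHANGE_COLUMNS = (
    "tampa_chg",
    "vas_chg",
    "eq5d_chg",
    "head_chg",
    "left_chg",
    "right_chg",
)


class RehabSenseError(Exception):
    """Base class for pipeline errors."""


class FormatError(RehabSenseError):
    """A stream or table could not be parsed."""


class SchemaError(RehabSenseError):
    """A delimited table is missing or misusing required columns."""


class InsufficientDataError(RehabSenseError):
    """Too few usable observations for the requested computation."""


class DegenerateDesignError(InsufficientDataError):
    """A regression design with no spread in the predictor."""


class SpecError(RehabSenseError):
    """An invalid simulation specification."""


class ValidationError(RehabSenseError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class SensorSample:
    """One position sample from one sensor.

    ``t`` is seconds since session start; ``x``, ``y``, ``z`` are meters in
    the device's world frame.
    """

    t: float
    x: float
    y: float
    z: float
    sensor: str

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValidationError(f"unknown sensor label {self.sensor!r}")
        if not all(map(math.isfinite, (self.t, self.x, self.y, self.z))):
            raise ValidationError("sample has non-finite timestamp or coordinate")


@dataclass
class MotionSegment:
    """One metadata-tagged run of tri-axial samples for a single sensor.

    Samples are stored as arrays: ``t`` with shape (n,) and ``xyz`` with
    shape (n, 3), timestamp-ordered.
    """

    segment_id: str
    sensor: str
    tag: str
    study_day: int
    t: np.ndarray
    xyz: np.ndarray
    action_class: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.sensor not in SENSORS:
            raise ValidationError(f"unknown sensor label {self.sensor!r}")
        if self.study_day < 1:
            raise ValidationError("study_day must be >= 1")
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValidationError("t must be (n,), xyz must be (n, 3)")
        if self.t.size and not (
            np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.xyz))
        ):
            raise ValidationError("non-finite sample values")
        if self.action_class is not None and self.action_class not in ACTION_CLASSES:
            raise ValidationError(f"unknown action class {self.action_class!r}")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def is_action(self) -> bool:
        return self.action_class == ACTION

    def samples(self) -> Iterator[SensorSample]:
        """Iterate samples as :class:`SensorSample` objects."""
        for ti, (xi, yi, zi) in zip(self.t, self.xyz):
            yield SensorSample(float(ti), float(xi), float(yi), float(zi), self.sensor)


@dataclass
class ParticipantMotionSeries:
    """All motion segments of one participant, across sensors and days."""

    participant_id: str
    arm: str
    segments: list[MotionSegment] = field(default_factory=list)
    #: per-sensor true daily velocity slope, set by the simulator only
    true_slopes: dict[str, float] | None = None

    @property
    def vr_study_day_count(self) -> int:
        """Number of distinct VR study days with any recorded segment."""
        return len({s.study_day for s in self.segments})

    def sensor_segments(self, sensor: str) -> list[MotionSegment]:
        return [s for s in self.segments if s.sensor == sensor]


@dataclass
class ClinicalChange:
    """Per-participant endpoint changes, end of treatment minus baseline.

    Sign conventions: a negative Tampa (kinesiophobia) change and a negative
    EQ-5D-5L index change are improvements; a positive overall-health VAS
    change is an improvement.  ``None`` marks a missing endpoint.
    """

    participant_id: str
    tampa_chg: float | None
    vas_chg: float | None
    eq5d_chg: float | None

    def __post_init__(self) -> None:
        if self.tampa_chg is not None and abs(self.tampa_chg) > 68:
            raise ValidationError("TSK change outside [-68, 68]")
        if self.vas_chg is not None and abs(self.vas_chg) > 100:
            raise ValidationError("VAS change outside [-100, 100]")


@dataclass
class ChangeEstimate:
    """Fitted velocity change for one participant and sensor.

    ``slope`` is m/s per study day from OLS of action-segment mean velocity
    on study-day ordinal; ``change`` is slope times the participant's count
    of VR study days (the estimate of velocity change over the study).
    """

    participant_id: str
    sensor: str
    slope: float
    change: float
    n_segments: int
    vr_study_day_count: int

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValidationError("a change estimate needs >= 2 segments")
        expected = self.slope * self.vr_study_day_count
        if not math.isclose(self.change, expected, rel_tol=0, abs_tol=1e-12):
            raise ValidationError("change must equal slope * vr_study_day_count")


@dataclass
class EdaSegment:
    """One segment of skin-conductance samples (microsiemens, nominal 4 Hz)."""

    segment_id: str
    study_day: int
    t: np.ndarray
    values: np.ndarray
    action_class: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise ValidationError("t and values must be equal-length 1-d arrays")
        if self.t.size:
            if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.values))):
                raise ValidationError("non-finite EDA values")
            if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
                raise ValidationError("EDA timestamps must be increasing")

    @property
    def duration_minutes(self) -> float:
        return float(self.t[-1] - self.t[0]) / 60.0 if self.t.size > 1 else 0.0


@dataclass
class EdaSeries:
    """All EDA segments of one participant."""

    participant_id: str
    arm: str
    segments: list[EdaSegment] = field(default_factory=list)


@dataclass
class EdaSegmentStats:
    """Phasic peak statistics for one EDA segment.

    Peaks are first differences above the segment's band, band =
    median + 2 * MAD of the differenced signal; ``degenerate_band`` flags
    segments where MAD collapsed to 0 and the band is the bare median.
    """

    segment_id: str
    participant_id: str
    arm: str
    median_delta: float
    mad_delta: float
    peak_count: int
    duration_minutes: float
    peaks_per_minute: float
    degenerate_band: bool = False

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise ValidationError("duration must be positive")
        if self.mad_delta < 0 or self.peak_count < 0:
            raise ValidationError("negative MAD or peak count")
        expected = self.peak_count / self.duration_minutes
        if not math.isclose(self.peaks_per_minute, expected, rel_tol=1e-12, abs_tol=0):
            raise ValidationError("peaks_per_minute must equal count / minutes")


@dataclass
class ActivityDay:
    """Daily activity aggregates from the wrist tracker."""

    participant_id: str
    arm: str
    study_day: int
    steps: int
    heart_rate_mean: float | None = None
    sleep_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.study_day < 1:
            raise ValidationError("study_day must be >= 1")
        if self.steps < 0:
            raise ValidationError("steps must be non-negative")
        if self.sleep_minutes is not None and self.sleep_minutes < 0:
            raise ValidationError("sleep_minutes must be non-negative")


@dataclass
class CorrelationReport:
    """A square correlation matrix over the six change variables.

    ``matrix`` is a symmetric DataFrame with unit diagonal; ``n_used`` is the
    number of complete rows after exclusion and listwise deletion;
    ``undefined`` lists variables whose column had zero variance (their
    off-diagonal entries are NaN by construction, flagged here rather than
    silently).
    """

    method: str
    variables: tuple[str, ...]
    matrix: pd.DataFrame
    n_used: int
    excluded_participants: tuple[str, ...] = ()
    undefined: tuple[str, ...] = ()


def validate_cohort_change_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort change table and return it with canonical columns.

    Expects a ``participant_id`` column plus the six change columns in
    :data:`CHANGE_COLUMNS`.  Participant ids must be unique.
    """
    missing = {"participant_id", *CHANGE_COLUMNS} - set(table.columns)
    if missing:
        raise SchemaError(f"cohort change table missing columns: {sorted(missing)}")
    if table["participant_id"].duplicated().any():
        raise ValidationError("duplicate participant_id in cohort change table")
    out = table.copy()
    out["participant_id"] = out["participant_id"].astype(str)
    for col in CHANGE_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="raise")
    return out
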