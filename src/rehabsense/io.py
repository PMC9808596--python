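"""Readers and writers for the pipeline's plain-text data formats.

All formats are line-oriented delimited text (comma-separated, UTF-8, header
row), so any stage's input or output can be inspected with ordinary tools.

Motion record streams
---------------------
One position record per line with the header::

    participant,day,sensor,tag,t,x,y,z

``day`` is the 1-based VR study-day ordinal, ``sensor`` one of
``head``/``left``/``right``, ``tag`` the VR software's metadata label for
the running sequence, ``t`` seconds since session start, and ``x,y,z``
position coordinates in meters.  Consecutive records sharing (day, sensor,
tag-run) form one motion segment.  This schema is this package's own; the
original trial's backend export format was not published.

The per-participant reference cohort (12 participants of the VR-treatment
arm with their clinical endpoint changes and fitted velocity changes) ships
as a packaged CSV, loaded by :func:`load_reference_cohort`.
"""

from __future__ import annotations

import csv
import importlib.resources
import io as _io
import warnings
from collections import defaultdict
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .types import (
    ARMS,
    ARM_DTXP,
    SENSORS,
    ActivityDay,
    ClinicalChange,
    EdaSegment,
    EdaSeries,
    FormatError,
    InsufficientDataError,
    MotionSegment,
    ParticipantMotionSeries,
    SchemaError,
    ValidationError,
    validate_cohort_change_table,
)

MOTION_FIELDS = ("participant", "day", "sensor", "tag", "t", "x", "y", "z")


def _open(source: str | Path | IO[str], mode: str = "r") -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline="")
    return source


# ---------------------------------------------------------------------------
# Motion record streams


def read_motion_records(
    source: str | Path | IO[str], arm: str = ARM_DTXP
) -> tuple[list[ParticipantMotionSeries], int]:
    """Parse a motion record stream into per-participant segment series.

    Records are grouped into segments on change of (participant, day,
    sensor, tag) between consecutive lines, preserving input order within a
    segment.  Malformed records (missing or non-numeric fields, unknown
    sensor) are counted and skipped rather than fatal.

    Returns ``(series_list, n_skipped)``.

    Raises
    ------
    FormatError
        If the header is unusable (names the offending line).
    InsufficientDataError
        If the stream contains zero valid records.
    """
    fh = _open(source)
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except (StopIteration, csv.Error) as exc:
        raise FormatError(f"unreadable motion stream at line 1: {exc}") from exc
    if tuple(h.strip() for h in header) != MOTION_FIELDS:
        raise FormatError(
            f"line 1: expected header {','.join(MOTION_FIELDS)}, got {','.join(header)}"
        )

    n_skipped = 0
    # rows per (participant, run): runs delimited by change of grouping key
    runs: dict[str, list[tuple]] = defaultdict(list)
    prev_key = None
    run_idx = 0
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(MOTION_FIELDS):
            n_skipped += 1
            continue
        pid, day_s, sensor, tag = (c.strip() for c in row[:4])
        try:
            day = int(day_s)
            t, x, y, z = (float(c) for c in row[4:])
        except ValueError:
            n_skipped += 1
            continue
        if sensor not in SENSORS or day < 1 or not np.isfinite([t, x, y, z]).all():
            n_skipped += 1
            continue
        key = (pid, day, sensor, tag)
        if key != prev_key:
            run_idx += 1
            prev_key = key
        runs[pid].append((run_idx, day, sensor, tag, t, x, y, z))

    if not runs:
        raise InsufficientDataError("motion stream contained zero valid records")

    series = []
    for pid in sorted(runs):
        segments = []
        rows = runs[pid]
        by_run: dict[int, list[tuple]] = defaultdict(list)
        for r in rows:
            by_run[r[0]].append(r)
        for run in sorted(by_run):
            rs = by_run[run]
            _, day, sensor, tag = rs[0][:4]
            t = np.array([r[4] for r in rs])
            xyz = np.array([[r[5], r[6], r[7]] for r in rs])
            segments.append(
                MotionSegment(
                    segment_id=f"{pid}-{run}",
                    sensor=sensor,
                    tag=tag,
                    study_day=day,
                    t=t,
                    xyz=xyz,
                )
            )
        series.append(ParticipantMotionSeries(pid, arm, segments))
    return series, n_skipped


def write_motion_records(
    series: Iterable[ParticipantMotionSeries], dest: str | Path | IO[str]
) -> None:
    """Write motion series as a record stream (inverse of the reader)."""
    fh = _open(dest, "w")
    writer = csv.writer(fh)
    writer.writerow(MOTION_FIELDS)
    for s in series:
        for seg in s.segments:
            for ti, (xi, yi, zi) in zip(seg.t, seg.xyz):
                writer.writerow(
                    [
                        s.participant_id,
                        seg.study_day,
                        seg.sensor,
                        seg.tag,
                        repr(float(ti)),
                        repr(float(xi)),
                        repr(float(yi)),
                        repr(float(zi)),
                    ]
                )
    if isinstance(dest, (str, Path)):
        fh.close()


# ---------------------------------------------------------------------------
# Clinical change tables

CLINICAL_FIELDS = ("participant_id", "tampa_chg", "vas_chg", "eq5d_chg")


def read_clinical(source: str | Path | IO[str]) -> list[ClinicalChange]:
    """Read per-participant clinical endpoint changes from a CSV.

    Blank cells are preserved as missing (``None``); they are dropped later
    by listwise deletion at correlation time, not here.
    """
    df = pd.read_csv(_open(source), float_precision="round_trip")
    unknown = set(df.columns) - set(CLINICAL_FIELDS)
    missing = set(CLINICAL_FIELDS) - set(df.columns)
    if unknown or missing:
        raise SchemaError(
            f"clinical table columns {sorted(df.columns)}; "
            f"expected exactly {list(CLINICAL_FIELDS)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            ClinicalChange(
                participant_id=str(row["participant_id"]),
                tampa_chg=None if pd.isna(row["tampa_chg"]) else float(row["tampa_chg"]),
                vas_chg=None if pd.isna(row["vas_chg"]) else float(row["vas_chg"]),
                eq5d_chg=None if pd.isna(row["eq5d_chg"]) else float(row["eq5d_chg"]),
            )
        )
    return out


def write_clinical(changes: Iterable[ClinicalChange], dest: str | Path | IO[str]) -> None:
    fh = _open(dest, "w")
    writer = csv.writer(fh)
    writer.writerow(CLINICAL_FIELDS)
    for c in changes:
        writer.writerow(
            [
                c.participant_id,
                "" if c.tampa_chg is None else c.tampa_chg,
                "" if c.vas_chg is None else c.vas_chg,
                "" if c.eq5d_chg is None else c.eq5d_chg,
            ]
        )
    if isinstance(dest, (str, Path)):
        fh.close()


# ---------------------------------------------------------------------------
# EDA tables

EDA_FIELDS = ("participant", "arm", "segment", "day", "label", "t", "value")


def read_eda(source: str | Path | IO[str]) -> list[EdaSeries]:
    """Read skin-conductance samples from a long-format CSV.

    Columns: participant, arm, segment (id), day, label (action class or
    empty), t (seconds), value (microsiemens).  Samples keep file order
    within a segment.
    """
    df = pd.read_csv(
        _open(source),
        dtype={"participant": str, "segment": str},
        float_precision="round_trip",
    )
    if tuple(df.columns) != EDA_FIELDS:
        raise SchemaError(f"EDA table columns {list(df.columns)}; expected {list(EDA_FIELDS)}")
    if not df["arm"].isin(ARMS).all():
        raise ValidationError("unknown arm label in EDA table")
    out = []
    for pid, pgroup in df.groupby("participant", sort=True):
        arm = pgroup["arm"].iloc[0]
        segments = []
        for seg_id, g in pgroup.groupby("segment", sort=False):
            label = g["label"].iloc[0]
            segments.append(
                EdaSegment(
                    segment_id=str(seg_id),
                    study_day=int(g["day"].iloc[0]),
                    t=g["t"].to_numpy(float),
                    values=g["value"].to_numpy(float),
                    action_class=None if pd.isna(label) else str(label),
                )
            )
        out.append(EdaSeries(str(pid), arm, segments))
    return out


def write_eda(series: Iterable[EdaSeries], dest: str | Path | IO[str]) -> None:
    fh = _open(dest, "w")
    writer = csv.writer(fh)
    writer.writerow(EDA_FIELDS)
    for s in series:
        for seg in s.segments:
            for ti, vi in zip(seg.t, seg.values):
                writer.writerow(
                    [
                        s.participant_id,
                        s.arm,
                        seg.segment_id,
                        seg.study_day,
                        seg.action_class or "",
                        repr(float(ti)),
                        repr(float(vi)),
                    ]
                )
    if isinstance(dest, (str, Path)):
        fh.close()


# ---------------------------------------------------------------------------
# Activity tables

ACTIVITY_FIELDS = ("participant", "arm", "day", "steps", "heart_rate_mean", "sleep_minutes")


def read_activity(source: str | Path | IO[str]) -> list[ActivityDay]:
    """Read daily activity aggregates; negative step counts are rejected."""
    df = pd.read_csv(
        _open(source), dtype={"participant": str}, float_precision="round_trip"
    )
    if tuple(df.columns) != ACTIVITY_FIELDS:
        raise SchemaError(
            f"activity table columns {list(df.columns)}; expected {list(ACTIVITY_FIELDS)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            ActivityDay(
                participant_id=str(row["participant"]),
                arm=str(row["arm"]),
                study_day=int(row["day"]),
                steps=int(row["steps"]),
                heart_rate_mean=None
                if pd.isna(row["heart_rate_mean"])
                else float(row["heart_rate_mean"]),
                sleep_minutes=None
                if pd.isna(row["sleep_minutes"])
                else float(row["sleep_minutes"]),
            )
        )
    return out


def write_activity(days: Iterable[ActivityDay], dest: str | Path | IO[str]) -> None:
    fh = _open(dest, "w")
    writer = csv.writer(fh)
    writer.writerow(ACTIVITY_FIELDS)
    for d in days:
        writer.writerow(
            [
                d.participant_id,
                d.arm,
                d.study_day,
                d.steps,
                "" if d.heart_rate_mean is None else d.heart_rate_mean,
                "" if d.sleep_minutes is None else d.sleep_minutes,
            ]
        )
    if isinstance(dest, (str, Path)):
        fh.close()


# ---------------------------------------------------------------------------
# Reference cohort fixture

SHORT_PARTICIPATION_STUDY_DAYS = 11  # VR study days of the short-participation row


def load_reference_cohort() -> pd.DataFrame:
    """Load the packaged per-participant change table of the treatment arm.

    Twelve rows, one per participant of the VR-treatment arm: clinical
    endpoint changes (``tampa_chg``, ``vas_chg``, ``eq5d_chg``, integer
    scales) and the fitted velocity changes of the three sensors
    (``head_chg``, ``left_chg``, ``right_chg``, m/s over the study, i.e.
    regression slope times VR study days).  The ``short_participation``
    flag marks the one participant with only 11 VR study days (versus 29-30
    for the rest); robustness analyses exclude that row at analysis time
    rather than here.
    """
    ref = importlib.resources.files("rehabsense").joinpath("data/reference_cohort.csv")
    try:
        text = ref.read_text(encoding="utf-8")
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise FormatError("packaged reference cohort fixture is missing") from exc
    df = pd.read_csv(_io.StringIO(text), dtype={"participant_id": str})
    df["short_participation"] = df["short_participation"].astype(bool)
    if len(df) != 12 or df["short_participation"].sum() != 1:
        raise FormatError("reference cohort fixture is corrupt")
    return validate_cohort_change_table(df)
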