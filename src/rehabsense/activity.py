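"""Daily-activity trends: weekly step changes and per-participant slopes.

Step counts from the wrist tracker are summarized two ways:

* weekly change from baseline — per participant, the mean daily steps of
  each study week minus the week-1 mean (weeks counted from randomization,
  ``week = ceil(day / 7)``, not calendar weeks, so arms stay aligned on
  study time);
* a two-stage trend model — ordinary least squares of steps on study day
  per participant, then per-arm mean/SD of the slopes and between-arm
  differences.  The two-stage form keeps every participant's own
  regression line while remaining fully specified and testable.

Heart rate and sleep are ingested and summarized descriptively only; daily
heart-rate aggregates carry too little precision for more.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd

from .types import ActivityDay, InsufficientDataError


def _activity_frame(days: list[ActivityDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in days],
            "arm": [d.arm for d in days],
            "study_day": [d.study_day for d in days],
            "steps": [d.steps for d in days],
        }
    )


def weekly_step_changes(days: list[ActivityDay]) -> pd.DataFrame:
    """Per participant-week mean daily steps and change from week 1.

    Week means use only the days present.  Participants with no week-1
    data have no baseline and are excluded with a warning.
    """
    if not days:
        raise InsufficientDataError("no activity days")
    df = _activity_frame(days)
    df["study_week"] = ((df["study_day"] - 1) // 7) + 1  # == ceil(day / 7)
    weekly = (
        df.groupby(["participant_id", "arm", "study_week"], sort=True)["steps"]
        .agg(mean_daily_steps="mean", n_days="size")
        .reset_index()
    )
    rows = []
    for (pid, arm), g in weekly.groupby(["participant_id", "arm"], sort=True):
        base = g.loc[g["study_week"] == 1, "mean_daily_steps"]
        if base.empty:
            warnings.warn(
                f"participant {pid}: no week-1 activity, excluded from weekly changes",
                stacklevel=2,
            )
            continue
        baseline = float(base.iloc[0])
        for _, r in g.iterrows():
            rows.append(
                {
                    "participant_id": pid,
                    "arm": arm,
                    "study_week": int(r["study_week"]),
                    "n_days": int(r["n_days"]),
                    "mean_daily_steps": float(r["mean_daily_steps"]),
                    "change_from_baseline": float(r["mean_daily_steps"]) - baseline,
                }
            )
    return pd.DataFrame(rows)


def participant_step_trends(
    days: list[ActivityDay],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant OLS step trends plus a per-arm summary.

    Stage 1 fits steps ~ study_day per participant (slope in steps/day);
    participants with fewer than two distinct days are excluded with a
    warning.  Stage 2 reports per-arm mean, SD and n of the slopes, and
    pairwise between-arm mean differences.

    Returns ``(slopes, arm_summary)``; ``arm_summary.attrs['differences']``
    holds the pairwise arm contrasts.
    """
    if not days:
        raise InsufficientDataError("no activity days")
    df = _activity_frame(days)
    rows = []
    for (pid, arm), g in df.groupby(["participant_id", "arm"], sort=True):
        if g["study_day"].nunique() < 2:
            warnings.warn(
                f"participant {pid}: fewer than 2 distinct days, trend excluded",
                stacklevel=2,
            )
            continue
        slope, intercept = np.polyfit(
            g["study_day"].to_numpy(float), g["steps"].to_numpy(float), 1
        )
        rows.append(
            {
                "participant_id": pid,
                "arm": arm,
                "slope_steps_per_day": float(slope),
                "intercept": float(intercept),
                "n_days": len(g),
            }
        )
    slopes = pd.DataFrame(rows)
    if slopes.empty:
        raise InsufficientDataError("no participant had a fittable step trend")
    arm_summary = (
        slopes.groupby("arm", sort=True)["slope_steps_per_day"]
        .agg(mean_slope="mean", sd_slope="std", n="size")
        .reset_index()
    )
    diffs = []
    means = dict(zip(arm_summary["arm"], arm_summary["mean_slope"]))
    for a, b in itertools.combinations(sorted(means), 2):
        diffs.append(
            {"arm_a": a, "arm_b": b, "mean_slope_difference": means[a] - means[b]}
        )
    arm_summary.attrs["differences"] = pd.DataFrame(diffs)
    return slopes, arm_summary


def descriptive_summary(days: list[ActivityDay]) -> pd.DataFrame:
    """Per-arm descriptive statistics of heart rate and sleep duration."""
    df = pd.DataFrame(
        {
            "arm": [d.arm for d in days],
            "heart_rate_mean": [
                math.nan if d.heart_rate_mean is None else d.heart_rate_mean
                for d in days
            ],
            "sleep_minutes": [
                math.nan if d.sleep_minutes is None else d.sleep_minutes for d in days
            ],
        }
    )
    return (
        df.groupby("arm", sort=True)
        .agg(["count", "mean", "std"])
        .reset_index()
    )
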