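"""End-to-end orchestration: simulate/ingest -> velocity -> slopes -> EDA ->
activity -> correlations, with a machine-readable run manifest.

Every stage writes a plain delimited table into the output directory so any
stage can be inspected or re-run standalone; the manifest records package
version, seed and the full configuration, which suffices to reproduce a run
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import participant_step_trends, weekly_step_changes
from .correlate import METHODS, correlation_matrix, robustness_compare, rounded
from .eda import arm_peak_summary, segment_stats
from .io import (
    load_reference_cohort,
    read_activity,
    read_eda,
    read_motion_records,
    write_activity,
    write_eda,
    write_motion_records,
)
from .simulate import (
    ACTION_TAG,
    CohortSpec,
    simulate_activity,
    simulate_clinical,
    simulate_eda,
    simulate_motion,
)
from .types import InsufficientDataError, RehabSenseError, SENSORS
from .velocity import classify_series, fit_daily_slope, segment_velocities

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``input_dir`` (pre-existing stream files) or
    ``simulation`` (a :class:`CohortSpec` to generate them) must be set,
    unless ``use_reference_cohort`` short-circuits straight to the
    correlation stage.
    """

    output_dir: str | Path = "rehabsense_out"
    input_dir: str | Path | None = None
    simulation: CohortSpec | None = None
    use_reference_cohort: bool = False
    action_tags: tuple[str, ...] = (ACTION_TAG,)
    gap_threshold: float = 0.5
    velocity_cap: float | None = None
    eda_band: str = "median"
    methods: tuple[str, ...] = METHODS
    exclude_short_participation: bool = True
    seed: int = 0

    def validate(self) -> None:
        n_sources = sum(
            [self.input_dir is not None, self.simulation is not None,
             self.use_reference_cohort]
        )
        if n_sources != 1:
            raise RehabSenseError(
                "exactly one of input_dir, simulation, use_reference_cohort "
                "must be set"
            )
        for m in self.methods:
            if m not in METHODS:
                raise RehabSenseError(f"unknown correlation method {m!r}")


def _write(df: pd.DataFrame, path: Path, name: str, written: dict) -> None:
    out = path / name
    df.to_csv(out, index=False, float_format="%.10g")
    written[name.removesuffix(".csv")] = str(out)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    A stage that signals insufficient data is skipped with a logged
    reason, as are downstream stages that need its output.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    skipped: dict[str, str] = {}

    spec = config.simulation
    if spec is not None:
        spec = spec.replace(seed=config.seed)

    # --- acquire streams -------------------------------------------------
    motion = eda = activity = clinical = None
    change_table = None
    flagged: list[str] = []
    if config.use_reference_cohort:
        change_table = load_reference_cohort()
        flagged = list(
            change_table.loc[change_table["short_participation"], "participant_id"]
        )
        skipped.update(
            {s: "reference cohort provides changes directly"
             for s in ("velocity", "slopes", "eda", "activity")}
        )
    elif spec is not None:
        motion = simulate_motion(spec)
        clinical = simulate_clinical(spec, motion)
        eda = simulate_eda(spec)
        activity = simulate_activity(spec)
        write_motion_records(motion, outdir / "motion_records.csv")
        written["motion_records"] = str(outdir / "motion_records.csv")
        write_eda(eda, outdir / "eda_records.csv")
        written["eda_records"] = str(outdir / "eda_records.csv")
        write_activity(activity, outdir / "activity_records.csv")
        written["activity_records"] = str(outdir / "activity_records.csv")
    else:
        indir = Path(config.input_dir)
        motion_path = indir / "motion_records.csv"
        if motion_path.exists():
            motion, n_skip = read_motion_records(motion_path)
            if n_skip:
                log.warning("motion stream: skipped %d malformed records", n_skip)
        eda_path = indir / "eda_records.csv"
        eda = read_eda(eda_path) if eda_path.exists() else None
        act_path = indir / "activity_records.csv"
        activity = read_activity(act_path) if act_path.exists() else None

    # --- velocity + slopes ----------------------------------------------
    if motion is not None:
        tags = set(config.action_tags)
        for series in motion:
            classify_series(series, tags)
        seg_rows = []
        for series in motion:
            for sv in segment_velocities(
                series, None, config.gap_threshold, config.velocity_cap
            ):
                seg_rows.append(
                    {
                        "participant_id": series.participant_id,
                        "segment_id": sv.segment_id,
                        "sensor": sv.sensor,
                        "study_day": sv.study_day,
                        "action_class": sv.action_class,
                        "mean_velocity": sv.mean_velocity,
                        "duration_s": sv.duration,
                        "n_points": sv.n_points,
                    }
                )
        _write(pd.DataFrame(seg_rows), outdir, "segment_velocities.csv", written)

        est_rows = []
        for series in motion:
            row: dict = {"participant_id": series.participant_id,
                         "vr_study_days": series.vr_study_day_count}
            ok = False
            for sensor in SENSORS:
                if not series.sensor_segments(sensor):
                    continue
                try:
                    est = fit_daily_slope(
                        series, sensor, config.gap_threshold, config.velocity_cap
                    )
                except InsufficientDataError as exc:
                    log.warning("slope skipped: %s", exc)
                    continue
                row[f"{sensor}_slope"] = est.slope
                row[f"{sensor}_chg"] = est.change
                ok = True
            if ok:
                est_rows.append(row)
        if est_rows:
            estimates = pd.DataFrame(est_rows)
            _write(estimates, outdir, "change_estimates.csv", written)
        else:
            skipped["slopes"] = "no participant had a fittable slope"

        # change table for correlations: movement + clinical changes
        if est_rows and clinical is not None:
            clin = pd.DataFrame(
                {
                    "participant_id": [c.participant_id for c in clinical],
                    "tampa_chg": [c.tampa_chg for c in clinical],
                    "vas_chg": [c.vas_chg for c in clinical],
                    "eq5d_chg": [c.eq5d_chg for c in clinical],
                }
            )
            movement = estimates[
                ["participant_id"]
                + [c for c in estimates.columns if c.endswith("_chg")]
            ]
            change_table = clin.merge(movement, on="participant_id", how="inner")

    # --- EDA --------------------------------------------------------------
    if eda is not None:
        stats = []
        for series in eda:
            stats.extend(segment_stats(series, band=config.eda_band))
        if stats:
            _write(
                pd.DataFrame([dataclasses.asdict(s) for s in stats]),
                outdir,
                "eda_segment_stats.csv",
                written,
            )
            _write(arm_peak_summary(stats), outdir, "eda_participant_summary.csv", written)
        else:
            skipped["eda"] = "no usable EDA segments"

    # --- activity ---------------------------------------------------------
    if activity is not None:
        _write(weekly_step_changes(activity), outdir, "weekly_step_changes.csv", written)
        try:
            slopes, arm_summary = participant_step_trends(activity)
            _write(slopes, outdir, "step_trends.csv", written)
            _write(arm_summary, outdir, "step_trend_arm_summary.csv", written)
        except InsufficientDataError as exc:
            skipped["activity_trends"] = str(exc)

    # --- correlations -----------------------------------------------------
    if change_table is not None:
        needed = {"tampa_chg", "vas_chg", "eq5d_chg", "head_chg", "left_chg", "right_chg"}
        if needed <= set(change_table.columns):
            for method in config.methods:
                try:
                    full, excl, diff = robustness_compare(
                        change_table, flagged, method=method
                    ) if flagged and config.exclude_short_participation else (
                        correlation_matrix(change_table, method=method),
                        None,
                        None,
                    )
                except InsufficientDataError as exc:
                    skipped[f"correlation_{method}"] = str(exc)
                    continue
                rounded(full).to_csv(outdir / f"correlation_{method}_full.csv")
                written[f"correlation_{method}_full"] = str(
                    outdir / f"correlation_{method}_full.csv"
                )
                if excl is not None:
                    rounded(excl).to_csv(outdir / f"correlation_{method}_excluded.csv")
                    written[f"correlation_{method}_excluded"] = str(
                        outdir / f"correlation_{method}_excluded.csv"
                    )
                    diff.round(4).to_csv(outdir / f"correlation_{method}_difference.csv")
                    written[f"correlation_{method}_difference"] = str(
                        outdir / f"correlation_{method}_difference.csv"
                    )
        else:
            skipped["correlations"] = "change table lacks movement or clinical columns"
    elif not config.use_reference_cohort:
        skipped["correlations"] = "no change table available"

    manifest = {
        "package": "rehabsense",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "outputs": written,
        "skipped_stages": skipped,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(d["output_dir"])
    if d["input_dir"] is not None:
        d["input_dir"] = str(d["input_dir"])
    return d
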