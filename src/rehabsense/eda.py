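"""Phasic electrodermal-activity analysis by differencing and MAD-band peaks.

Skin conductance mixes a slow tonic drift with fast phasic responses.  The
tonic component is removed by first differencing consecutive samples
(d_i = value_i - value_{i-1}), which makes the signal stationary: a constant
offset vanishes and a linear drift becomes a constant.  Phasic activity is
then quantified as the number of differences above a robust per-segment
band,

    band = median(d) + 2 * MAD(d),      MAD = median(|x_i - median(x)|),

normalized to peaks per minute by the segment's duration.  MAD is preferred
over the standard deviation because peaks are exactly the outliers the
standard deviation would be inflated by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ARM_DTXP,
    NO_ACTION_START_OF_DAY,
    EdaSegment,
    EdaSegmentStats,
    EdaSeries,
    InsufficientDataError,
    RehabSenseError,
)


@dataclass
class PhasicSeries:
    """First differences of one EDA segment; one element per sample pair.

    ``t`` keeps the later timestamp of each pair, ``deltas`` the change in
    microsiemens.
    """

    segment_id: str
    t: np.ndarray
    deltas: np.ndarray


def phasic_differences(segment: EdaSegment) -> PhasicSeries:
    """Difference consecutive samples to isolate the phasic component."""
    if segment.t.size < 2:
        raise InsufficientDataError(
            f"EDA segment {segment.segment_id}: need >= 2 samples"
        )
    return PhasicSeries(
        segment_id=segment.segment_id,
        t=segment.t[1:].copy(),
        deltas=np.diff(segment.values),
    )


def mad(values) -> float:
    """Median absolute deviation, median(|x_i - median(x)|).

    Even-length medians use the midpoint convention.  Robust scale measure:
    unaffected by a few extreme values, which is what makes it a usable
    peak band for a signal whose peaks are the outliers of interest.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad() of empty sequence")
    return float(np.median(np.abs(x - np.median(x))))


def count_peaks(
    phasic: PhasicSeries,
    segment: EdaSegment,
    participant_id: str = "",
    arm: str = "",
    band: str = "median",
) -> EdaSegmentStats:
    """Count differenced-signal peaks above the segment's MAD band.

    A peak is a difference strictly above ``median + 2 * MAD`` (``band =
    "median"``, default) or strictly above ``2 * MAD`` alone (``band =
    "zero"``, the alternative anchoring).  When MAD degenerates to 0 (e.g.
    quantized flat signal) the band collapses to its anchor and the segment
    is flagged ``degenerate_band``.  Duration comes from timestamps, not
    sample count, so dropped samples do not bias the per-minute rate.
    """
    if phasic.deltas.size == 0:
        raise InsufficientDataError(f"segment {phasic.segment_id}: empty phasic series")
    if band not in ("median", "zero"):
        raise ValueError(f"unknown band variant {band!r}")
    duration_min = segment.duration_minutes
    if duration_min <= 0:
        raise ValueError(f"segment {phasic.segment_id}: non-positive duration")
    med = float(np.median(phasic.deltas))
    m = mad(phasic.deltas)
    threshold = (med if band == "median" else 0.0) + 2.0 * m
    peak_count = int(np.sum(phasic.deltas > threshold))
    return EdaSegmentStats(
        segment_id=phasic.segment_id,
        participant_id=participant_id,
        arm=arm,
        median_delta=med,
        mad_delta=m,
        peak_count=peak_count,
        duration_minutes=duration_min,
        peaks_per_minute=peak_count / duration_min,
        degenerate_band=(m == 0.0),
    )


def filter_start_of_day(series: EdaSeries) -> EdaSeries:
    """Drop start-of-day segments from treatment-arm series.

    Treatment-arm recordings before the day's first VR task are removed so
    that the active phase is compared against comparator-arm data, which is
    assumed to consist entirely of no-action segments and passes through
    unchanged.
    """
    if series.arm != ARM_DTXP:
        return series
    kept = [s for s in series.segments if s.action_class != NO_ACTION_START_OF_DAY]
    return EdaSeries(series.participant_id, series.arm, kept)


def segment_stats(
    series: EdaSeries, band: str = "median", drop_start_of_day: bool = True
) -> list[EdaSegmentStats]:
    """Peak statistics for every usable segment of one participant."""
    src = filter_start_of_day(series) if drop_start_of_day else series
    out = []
    for seg in src.segments:
        try:
            phasic = phasic_differences(seg)
            out.append(
                count_peaks(phasic, seg, series.participant_id, series.arm, band=band)
            )
        except (InsufficientDataError, ValueError):
            continue
    return out


def arm_peak_summary(stats: list[EdaSegmentStats]) -> pd.DataFrame:
    """Per-participant peaks/minute distribution, ordered by median.

    One row per participant with median, quartiles and segment count of
    peaks-per-minute, sorted ascending by median (ties broken by
    participant id) — the layout used to compare arms visually.
    """
    if not stats:
        raise RehabSenseError("no EDA segment statistics to summarize")
    df = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in stats],
            "arm": [s.arm for s in stats],
            "peaks_per_minute": [s.peaks_per_minute for s in stats],
        }
    )
    rows = []
    for (pid, arm), g in df.groupby(["participant_id", "arm"], sort=True):
        v = g["peaks_per_minute"]
        rows.append(
            {
                "participant_id": pid,
                "arm": arm,
                "n_segments": len(g),
                "q25": v.quantile(0.25),
                "median": v.median(),
                "q75": v.quantile(0.75),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["median", "participant_id"], kind="stable", ignore_index=True
    )
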