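"""Clinical endpoint changes and movement-clinical correlation matrices.

The association between movement improvement and clinical improvement is
assessed by correlating, across participants, the per-sensor velocity
change (regression slope times VR study days) with the change from baseline
at end of treatment in three clinical endpoints (Tampa Scale of
Kinesiophobia, EQ-5D overall-health VAS, EQ-5D-5L index).  Both the
product-moment (Pearson) and the rank (Spearman) coefficient are computed:
with a dozen participants a single observation can swing the parametric
value, so the rank version serves as a robustness companion.  Rows with any
missing value among the six variables are removed listwise before either
matrix; robustness to the one short-participation participant is assessed
by computing the matrices with and without that row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import (
    CHANGE_COLUMNS,
    ClinicalChange,
    CorrelationReport,
    InsufficientDataError,
    validate_cohort_change_table,
)

#: Display names of the correlated variables, in matrix order.
VARIABLE_LABELS = {
    "tampa_chg": "TampaChg",
    "vas_chg": "VASChg",
    "eq5d_chg": "EQ5DChg",
    "head_chg": "HeadChg",
    "left_chg": "LeftChg",
    "right_chg": "RightChg",
}

METHODS = ("pearson", "spearman")


def clinical_changes(
    participant_id: str,
    baseline: dict[str, float | None],
    end_of_treatment: dict[str, float | None],
) -> ClinicalChange:
    """End-of-treatment minus baseline for the three clinical endpoints.

    ``baseline`` and ``end_of_treatment`` map endpoint keys (``tampa``,
    ``vas``, ``eq5d``) to scores; a missing score at either timepoint makes
    that endpoint's change missing (``None``).
    """
    out: dict[str, float | None] = {}
    for key in ("tampa", "vas", "eq5d"):
        b, e = baseline.get(key), end_of_treatment.get(key)
        if b is None or e is None:
            import warnings

            warnings.warn(
                f"participant {participant_id}: endpoint {key} missing at a "
                "timepoint; change set to missing",
                stacklevel=2,
            )
            out[key] = None
        else:
            out[key] = e - b
    return ClinicalChange(participant_id, out["tampa"], out["vas"], out["eq5d"])


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Product-moment correlation of columns; zero-variance columns -> NaN."""
    x = x - x.mean(axis=0)
    ss = np.sqrt((x**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ x) / np.outer(ss, ss)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r[ss == 0, :] = np.nan
    r[:, ss == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def correlation_matrix(
    table: pd.DataFrame,
    method: str = "pearson",
    exclude: tuple[str, ...] | list[str] = (),
) -> CorrelationReport:
    """Correlation matrix over the six change variables with listwise deletion.

    Pearson is the product-moment coefficient on the raw values; Spearman
    is Pearson applied to midranks (ties receive their average rank).
    Participants in ``exclude`` are dropped first, then any row with a
    missing value in any of the six variables is removed listwise.  A
    zero-variance column yields NaN entries, flagged in ``undefined``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    table = validate_cohort_change_table(table)
    exclude = tuple(str(e) for e in exclude)
    kept = table[~table["participant_id"].isin(exclude)]
    complete = kept.dropna(subset=list(CHANGE_COLUMNS))
    if len(complete) < 3:
        raise InsufficientDataError(
            f"{len(complete)} complete rows after exclusion/listwise deletion; need >= 3"
        )
    x = complete[list(CHANGE_COLUMNS)].to_numpy(float)
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 0, x)  # midranks
    r = _pearson_matrix(x)
    labels = [VARIABLE_LABELS[c] for c in CHANGE_COLUMNS]
    matrix = pd.DataFrame(r, index=labels, columns=labels)
    undefined = tuple(
        VARIABLE_LABELS[c]
        for c, s in zip(CHANGE_COLUMNS, x.std(axis=0))
        if s == 0
    )
    return CorrelationReport(
        method=method,
        variables=tuple(labels),
        matrix=matrix,
        n_used=len(complete),
        excluded_participants=exclude,
        undefined=undefined,
    )


def robustness_compare(
    table: pd.DataFrame,
    flagged: tuple[str, ...] | list[str],
    method: str = "pearson",
) -> tuple[CorrelationReport, CorrelationReport, pd.DataFrame]:
    """Correlation matrices with the full table and with flagged rows removed.

    Returns ``(full, excluded, difference)`` where ``difference`` is the
    elementwise full-minus-excluded matrix — the robustness check for
    participants whose data coverage differs from the rest (e.g. the one
    with two-thirds of study days missing).
    """
    table = validate_cohort_change_table(table)
    flagged = tuple(str(f) for f in flagged)
    present = set(table["participant_id"])
    missing = [f for f in flagged if f not in present]
    if missing:
        raise ValueError(f"flagged participants not in table: {missing}")
    full = correlation_matrix(table, method=method)
    excluded = correlation_matrix(table, method=method, exclude=flagged)
    difference = full.matrix - excluded.matrix
    return full, excluded, difference


def rounded(report: CorrelationReport, decimals: int = 2) -> pd.DataFrame:
    """The report's matrix rounded for display (full precision kept inside)."""
    return report.matrix.round(decimals)
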