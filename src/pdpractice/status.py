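"""Cognitive status from MoCA and derivation of time-to-event outcomes.

Global cognition is screened with the MoCA (0-30), education-corrected by
+1 point for subjects with <= 12 years of schooling (capped at 30).  Using
PD-specific cut-offs on the adjusted score: >= 26 intact, <= 25 cognitive
impairment (CI), <= 21 dementia-level impairment (PDD).  For each subject the
event month is the first visit at which the adjusted score crosses below the
respective cut-off; subjects who never cross are right-censored at their last
observed MoCA visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StatusThresholds:
    """MoCA cut-offs and education-correction rule."""

    intact_min: int = 26
    ci_max: int = 25
    pdd_max: int = 21
    education_correction_years: int = 12
    education_correction_points: int = 1
    moca_ceiling: int = 30

    def __post_init__(self):
        if not (self.pdd_max < self.ci_max < self.intact_min):
            raise ValueError("thresholds must satisfy pdd_max < ci_max < intact_min")
        if self.intact_min != self.ci_max + 1:
            raise ValueError("intact_min must equal ci_max + 1")


DEFAULT_THRESHOLDS = StatusThresholds()


def adjust_moca(raw, education_years, thresholds: StatusThresholds = DEFAULT_THRESHOLDS):
    """Education-corrected MoCA: +1 point for <= 12 years of education,
    capped at the instrument ceiling of 30.  Vectorized."""
    raw_arr = np.asarray(raw, dtype=float)
    if np.any((raw_arr < 0) | (raw_arr > 30)):
        raise ValueError("raw MoCA scores must lie in [0, 30]")
    edu = np.asarray(education_years, dtype=float)
    adj = raw_arr + np.where(
        edu <= thresholds.education_correction_years,
        thresholds.education_correction_points,
        0,
    )
    adj = np.minimum(adj, thresholds.moca_ceiling)
    return adj if adj.ndim else float(adj)


def classify_status(adjusted, thresholds: StatusThresholds = DEFAULT_THRESHOLDS):
    """Map an adjusted MoCA score to 'intact' | 'CI' | 'PDD'.

    PDD implies CI for event purposes; this function returns the most severe
    applicable label.  Vectorized.
    """
    arr = np.asarray(adjusted, dtype=float)
    out = np.where(
        arr <= thresholds.pdd_max,
        "PDD",
        np.where(arr <= thresholds.ci_max, "CI", "intact"),
    )
    return out if arr.ndim else str(out)


def filter_baseline_intact(
    visits: pd.DataFrame,
    thresholds: StatusThresholds = DEFAULT_THRESHOLDS,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Inclusion filter: adjusted baseline MoCA >= intact_min AND a year-1
    battery retest visit.

    Returns (included subject ids, per-subject exclusion table with a
    ``reason`` column: ``no_baseline_moca``, ``baseline_not_intact`` or
    ``no_followup_battery``).
    """
    base = visits[visits["visit_index"] == 0].set_index("subject_id")
    has_fu = set(visits.loc[visits["visit_index"] == 1, "subject_id"])
    reasons = {}
    for sid, row in base.iterrows():
        raw = row["moca_raw"]
        if pd.isna(raw) or raw < 0:
            reasons[sid] = "no_baseline_moca"
            continue
        adj = adjust_moca(float(raw), float(row["education_years"]), thresholds)
        if adj < thresholds.intact_min:
            reasons[sid] = "baseline_not_intact"
        elif sid not in has_fu:
            reasons[sid] = "no_followup_battery"
    excluded = pd.DataFrame(
        {"subject_id": list(reasons), "reason": list(reasons.values())}
    )
    included = base.index[~base.index.isin(reasons)].to_series(name="subject_id")
    return included.reset_index(drop=True), excluded


def derive_event_times(
    months: Sequence[float],
    adjusted_moca: Sequence[float],
    thresholds: StatusThresholds = DEFAULT_THRESHOLDS,
    sustained_visits: int = 1,
) -> dict:
    """Derive CI/PDD event indicators and onset months for one subject.

    The onset month is the first visit whose adjusted MoCA is at or below the
    cut-off (optionally required to be sustained for ``sustained_visits``
    consecutive visits); a first crossing straight to the PDD band sets both
    events at the same month.  Subjects who never cross are censored at the
    last visit month.
    """
    months = np.asarray(months, dtype=float)
    adj = np.asarray(adjusted_moca, dtype=float)
    if months.size == 0:
        raise ValueError("empty MoCA series")
    if np.any(np.diff(months) <= 0):
        raise ValueError("visit months must be strictly increasing")
    if months.shape != adj.shape:
        raise ValueError("months and MoCA series have different lengths")

    def first_crossing(cutoff: float) -> Optional[float]:
        below = adj <= cutoff
        run = 0
        for j in range(below.size):
            run = run + 1 if below[j] else 0
            if run >= sustained_visits:
                return float(months[j - sustained_visits + 1])
        return None

    ci_t = first_crossing(thresholds.ci_max)
    pdd_t = first_crossing(thresholds.pdd_max)
    censor = float(months[-1])
    return {
        "ci_event": ci_t is not None,
        "ci_time": ci_t if ci_t is not None else censor,
        "pdd_event": pdd_t is not None,
        "pdd_time": pdd_t if pdd_t is not None else censor,
        "censor_time": censor,
    }


def derive_outcomes(
    visits: pd.DataFrame,
    thresholds: StatusThresholds = DEFAULT_THRESHOLDS,
    group: Optional[str] = "PD",
    sustained_visits: int = 1,
) -> pd.DataFrame:
    """Per-subject outcome records for a cohort visit table.

    Education-corrects the raw MoCA per subject, then applies
    :func:`derive_event_times` to each subject's visit series.  ``group``
    restricts to one group (default PD, whose long-term outcomes the
    analysis concerns); pass None to keep everyone.
    """
    df = visits
    if group is not None:
        df = df[df["group"] == group]
    df = df[df["moca_raw"] >= 0]  # visits with a MoCA administration
    records = []
    for sid, sub in df.sort_values("visit_month").groupby("subject_id"):
        adj = adjust_moca(
            sub["moca_raw"].to_numpy(),
            sub["education_years"].to_numpy(),
            thresholds,
        )
        rec = derive_event_times(
            sub["visit_month"].to_numpy(), adj, thresholds, sustained_visits
        )
        rec["subject_id"] = sid
        records.append(rec)
    out = pd.DataFrame(
        records,
        columns=["ci_event", "ci_time", "pdd_event", "pdd_time",
                 "censor_time", "subject_id"],
    )
    return out[["subject_id", "ci_event", "ci_time", "pdd_event",
                "pdd_time", "censor_time"]].reset_index(drop=True)
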