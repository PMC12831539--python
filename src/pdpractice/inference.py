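"""The inferential battery over SRB practice-effect scores.

Four families of analyses:

* group comparisons — per test, OLS of the oriented SRB z on a PD indicator
  plus age, sex and education; the PD coefficient estimates how much smaller
  (in residual-SD units) the PD practice effect is than the HC one;
* change-category chi-squares — Pearson goodness-of-fit of the PD
  decline / no-change / improvement counts against either the HC observed
  proportions or the theoretical normal tails (0.05 / 0.90 / 0.05);
* Cox proportional-hazards prognosis — within PD, time to CI or PDD onset
  regressed on an SRB z-score (composite or single test) with age and sex;
  hazard ratios below 1 mean smaller practice effects carry higher risk;
  the proportional-hazards assumption is checked with scaled Schoenfeld
  residuals and non-linearity is probed with martingale residuals;
* multiplicity — Benjamini-Hochberg FDR over a single pooled array of
  p-values per outcome family.

Kaplan-Meier cumulative-incidence coordinates for a median split on the
practice-effect score are exported for visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .battery import TEST_NAMES
from .srb import CATEGORIES

#: theoretical trichotomization proportions under the standard normal
NORMAL_REFERENCE = {"decline": 0.05, "no_change": 0.90, "improvement": 0.05}


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    test: str
    beta_group: float
    se: float
    p: float
    n: int
    q: Optional[float] = None
    reason: Optional[str] = None

    @property
    def estimable(self) -> bool:
        return self.reason is None


def compare_groups(scores: pd.DataFrame, test: str) -> GroupComparisonResult:
    """PD-vs-HC difference in oriented SRB z for one test (or 'composite').

    OLS of z on a PD indicator (PD = 1, HC = 0), age, sex and education with
    an intercept; complete cases for that test.
    """
    col = "composite" if test == "composite" else f"z_{test}"
    df = scores[[col, "group", "age", "sex", "education_years"]].dropna()
    groups = set(df["group"])
    if not {"HC", "PD"} <= groups:
        return GroupComparisonResult(test, np.nan, np.nan, np.nan, len(df),
                                     reason="group_absent")
    X = sm.add_constant(
        pd.DataFrame(
            {
                "pd": (df["group"] == "PD").astype(float),
                "age": df["age"].astype(float),
                "sex": df["sex"].astype(float),
                "education": df["education_years"].astype(float),
            }
        ),
        has_constant="add",
    )
    fit = sm.OLS(df[col].astype(float), X).fit()
    return GroupComparisonResult(
        test=test,
        beta_group=float(fit.params["pd"]),
        se=float(fit.bse["pd"]),
        p=float(fit.pvalues["pd"]),
        n=len(df),
    )


# --------------------------------------------------------------------------
# change-category chi-square
# --------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    test: str
    statistic: float
    df: int
    p: float
    observed: Dict[str, int]
    expected: Dict[str, float]
    mode: str = "hc"
    q: Optional[float] = None
    reason: Optional[str] = None

    @property
    def computable(self) -> bool:
        return self.reason is None


def chisq_change(
    pd_counts: Mapping[str, int],
    reference: Optional[Mapping[str, float]] = None,
    mode: str = "hc",
    test: str = "",
) -> ChiSquareResult:
    """Pearson goodness-of-fit of PD change-category counts.

    ``mode='hc'`` takes ``reference`` as HC counts (converted to
    proportions); ``mode='normal'`` uses the theoretical 0.05/0.90/0.05
    split.  An HC category with zero proportion but non-zero PD observations
    makes the HC-reference test non-computable (zero expected count); a
    category empty in both is dropped with the degrees of freedom reduced.
    """
    obs = np.array([float(pd_counts.get(c, 0)) for c in CATEGORIES])
    if obs.min() < 0 or obs.sum() <= 0:
        raise ValueError("PD counts must be non-negative with positive total")
    if mode == "normal":
        props = np.array([NORMAL_REFERENCE[c] for c in CATEGORIES])
    elif mode == "hc":
        if reference is None:
            raise ValueError("HC reference counts required in mode='hc'")
        ref = np.array([float(reference.get(c, 0)) for c in CATEGORIES])
        if ref.sum() <= 0:
            raise ValueError("reference counts must have positive total")
        props = ref / ref.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    keep = ~((props == 0) & (obs == 0))
    if np.any((props[keep] == 0) & (obs[keep] > 0)):
        return ChiSquareResult(
            test, np.nan, 0, np.nan,
            {c: int(o) for c, o in zip(CATEGORIES, obs)}, {}, mode,
            reason="zero_expected_category",
        )
    obs_k, props_k = obs[keep], props[keep]
    expected = obs.sum() * props_k / props_k.sum()
    if keep.sum() < 2:
        return ChiSquareResult(
            test, 0.0, 0, 1.0,
            {c: int(o) for c, o in zip(CATEGORIES, obs)},
            dict(zip(np.array(CATEGORIES)[keep], expected)), mode,
            reason="degenerate_single_category",
        )
    stat, p = stats.chisquare(obs_k, expected)
    return ChiSquareResult(
        test=test,
        statistic=float(stat),
        df=int(keep.sum() - 1),
        p=float(p),
        observed={c: int(o) for c, o in zip(CATEGORIES, obs)},
        expected=dict(zip(np.array(CATEGORIES)[keep], expected)),
        mode=mode,
    )


def category_counts(scores: pd.DataFrame, test: str, group: str) -> Dict[str, int]:
    """Counts of decline/no_change/improvement for one test in one group."""
    cats = scores.loc[scores["group"] == group, f"cat_{test}"].dropna()
    return {c: int((cats == c).sum()) for c in CATEGORIES}


# --------------------------------------------------------------------------
# Cox proportional-hazards prognosis
# --------------------------------------------------------------------------

@dataclass
class CoxResult:
    outcome: str
    predictor: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    centered: bool = False
    ph_test_p: Optional[float] = None
    ph_covariate_p: Dict[str, float] = field(default_factory=dict)
    linearity_p: Optional[float] = None
    q: Optional[float] = None
    reason: Optional[str] = None
    log_hr: float = np.nan
    se_log_hr: float = np.nan

    @property
    def estimable(self) -> bool:
        return self.reason is None


def center_predictor(values, enabled: bool = True):
    """Subtract the sample mean (used to resolve non-linearity diagnostics;
    a location shift leaves Cox hazard ratios unchanged)."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("predictor values must be finite")
    if not enabled:
        return values
    centered = arr - arr.mean()
    if isinstance(values, pd.Series):
        return pd.Series(centered, index=values.index)
    return centered


def fit_cox(
    outcomes: pd.DataFrame,
    scores: pd.DataFrame,
    predictor: str,
    outcome_type: str = "ci",
    center: bool = False,
    min_events: int = 2,
    covariates: tuple = ("age", "sex"),
) -> CoxResult:
    """Cox PH model of time-to-CI or time-to-PDD on one SRB score.

    ``predictor`` is 'composite' or a test name; default covariates are age
    and sex.
    Ties are handled with the Efron approximation (annual visit months make
    ties common).  Returns a not-estimable result (with a reason) when there
    are no events among complete cases, fewer than ``min_events`` events, or
    the predictor is constant.
    """
    if outcome_type not in ("ci", "pdd"):
        raise ValueError("outcome_type must be 'ci' or 'pdd'")
    col = "composite" if predictor == "composite" else f"z_{predictor}"
    covariates = tuple(covariates)
    merged = outcomes.merge(
        scores[["subject_id", col, *covariates]], on="subject_id", how="inner"
    )
    merged = merged.dropna(subset=[col, *covariates])
    dur = merged[f"{outcome_type}_time"].astype(float)
    evt = merged[f"{outcome_type}_event"].astype(bool)
    n, n_events = len(merged), int(evt.sum())

    def _na(reason):
        return CoxResult(outcome_type, predictor, np.nan, np.nan, np.nan,
                         np.nan, n, n_events, centered=center, reason=reason)

    if n_events == 0:
        return _na("no_events")
    if n_events < min_events:
        return _na("too_few_events")
    z = merged[col].astype(float)
    if z.nunique() <= 1:
        return _na("constant_predictor")
    z = center_predictor(z, center)
    df = pd.DataFrame(
        {"duration": dur.values, "event": evt.values.astype(int),
         "z": np.asarray(z, dtype=float),
         **{c: merged[c].astype(float).values for c in covariates}}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # convergence failure on degenerate data
        return _na(f"fit_failed: {type(exc).__name__}")
    row = cph.summary.loc["z"]
    result = CoxResult(
        outcome=outcome_type,
        predictor=predictor,
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        n=n,
        n_events=n_events,
        centered=center,
        log_hr=float(row["coef"]),
        se_log_hr=float(row["se(coef)"]),
    )
    ph = check_ph_assumption(cph, df)
    result.ph_test_p = ph.get("global")
    result.ph_covariate_p = {k: v for k, v in ph.items() if k != "global"}
    result.linearity_p = check_linearity(cph, df)
    return result


def check_ph_assumption(cph: CoxPHFitter, df: pd.DataFrame) -> Dict[str, float]:
    """Scaled-Schoenfeld-residual test of proportional hazards.

    Returns per-covariate p-values plus a 'global' p obtained by referring
    the sum of the per-covariate score statistics to a chi-square with as
    many degrees of freedom as covariates.  With fewer than two events the
    test is skipped and an empty dict returned.
    """
    if df["event"].sum() < 2:
        return {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(cph, df, time_transform="rank")
    stats_ = res.summary["test_statistic"]
    out = {name: float(p) for name, p in res.summary["p"].items()}
    total = float(stats_.sum())
    out["global"] = float(stats.chi2.sf(total, df=len(stats_)))
    return out


def check_linearity(cph: CoxPHFitter, df: pd.DataFrame) -> float:
    """Probe linearity of the predictor's log-hazard contribution.

    Correlates martingale residuals with the squared (centered) predictor; a
    small p suggests curvature, which mean-centering the predictor before a
    quadratic refit conventionally alleviates in reporting.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        resid = cph.compute_residuals(df, kind="martingale")["martingale"]
    zc = df.loc[resid.index, "z"] - df["z"].mean()
    if np.isclose(np.var(zc**2), 0):
        return np.nan
    r, p = stats.pearsonr(resid, zc**2)
    return float(p)


# --------------------------------------------------------------------------
# multiplicity
# --------------------------------------------------------------------------

def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values for one family.

    All inputs must be valid probabilities; pool the family into a single
    array before calling.
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# median-split cumulative incidence (visualization)
# --------------------------------------------------------------------------

def cumulative_incidence_by_split(
    outcomes: pd.DataFrame,
    scores: pd.DataFrame,
    predictor: str = "composite",
    outcome_type: str = "ci",
) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence (1 - S) for high vs low halves of
    the practice-effect score (median split; ties to the low half).

    Returns a long table: split, time, cum_incidence — coordinates for
    "reversed survival" curves.  Visualization aid only.
    """
    col = "composite" if predictor == "composite" else f"z_{predictor}"
    merged = outcomes.merge(
        scores[["subject_id", col]], on="subject_id", how="inner"
    ).dropna(subset=[col])
    z = merged[col].astype(float)
    med = z.median()
    split = np.where(z <= med, "low", "high")
    if (split == "low").all() or (split == "high").all():
        warnings.warn("constant practice-effect score: single-group curve")
        split[:] = "low"
    frames = []
    for half in ("low", "high"):
        mask = split == half
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(
            merged.loc[mask, f"{outcome_type}_time"],
            merged.loc[mask, f"{outcome_type}_event"].astype(bool),
        )
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"split": half, "time": sf.index.to_numpy(dtype=float),
                 "cum_incidence": 1.0 - sf.iloc[:, 0].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# assembled tables
# --------------------------------------------------------------------------

def group_comparison_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-test + composite PD-vs-HC comparison (q filled by the outcome
    families in :func:`full_analysis`)."""
    rows = [compare_groups(scores, t) for t in list(TEST_NAMES) + ["composite"]]
    return pd.DataFrame(
        [{"test": r.test, "beta_group": r.beta_group, "se": r.se, "p": r.p,
          "n": r.n, "reason": r.reason} for r in rows]
    )


def chisq_table(scores: pd.DataFrame, mode: str = "hc") -> pd.DataFrame:
    """Per-test change-category chi-square of PD against the reference.

    In HC-reference mode, tests whose HC sample has an empty category with
    PD observations fall back to the theoretical-normal reference (noted in
    the ``mode`` column).  q-values are BH-adjusted within this family.
    """
    rows = []
    for t in TEST_NAMES:
        pd_counts = category_counts(scores, t, "PD")
        if sum(pd_counts.values()) == 0:
            continue
        if mode == "hc":
            res = chisq_change(pd_counts, category_counts(scores, t, "HC"),
                               mode="hc", test=t)
            if not res.computable:
                res = chisq_change(pd_counts, mode="normal", test=t)
                res.reason = "hc_reference_zero_category_fallback_normal"
        else:
            res = chisq_change(pd_counts, mode="normal", test=t)
        rows.append(res)
    tab = pd.DataFrame(
        [{"test": r.test, "statistic": r.statistic, "df": r.df, "p": r.p,
          "mode": r.mode, "note": r.reason,
          **{f"obs_{c}": r.observed.get(c, 0) for c in CATEGORIES}}
         for r in rows]
    )
    ok = tab["p"].notna()
    tab["q"] = np.nan
    if ok.any():
        tab.loc[ok, "q"] = fdr_adjust(tab.loc[ok, "p"].to_numpy())
    return tab


def cox_table(
    outcomes: pd.DataFrame,
    scores: pd.DataFrame,
    outcome_type: str,
    center_map: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Composite + per-test Cox PH results for one outcome."""
    center_map = center_map or {}
    rows = []
    for pred in ["composite"] + list(TEST_NAMES):
        r = fit_cox(outcomes, scores, pred, outcome_type,
                    center=bool(center_map.get(pred, False)))
        rows.append(
            {"outcome": r.outcome, "predictor": r.predictor, "hr": r.hr,
             "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "n": r.n,
             "n_events": r.n_events, "centered": r.centered,
             "ph_global_p": r.ph_test_p, "linearity_p": r.linearity_p,
             "reason": r.reason}
        )
    return pd.DataFrame(rows)


def full_analysis(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    chisq_mode: str = "hc",
    center_map: Optional[Mapping[str, bool]] = None,
) -> Dict[str, pd.DataFrame]:
    """Run the whole inferential battery and apply the two FDR families.

    Each outcome family pools the group-comparison p-values with that
    outcome's Cox p-values into a single BH array; the group table reports
    the CI-family q.  Chi-squares are adjusted within their own family.
    """
    group_tab = group_comparison_table(scores)
    chis = chisq_table(scores, mode=chisq_mode)
    cox_ci = cox_table(outcomes, scores, "ci", center_map)
    cox_pdd = cox_table(outcomes, scores, "pdd", center_map)

    for cox, attach_group in ((cox_ci, True), (cox_pdd, False)):
        g_ok = group_tab["p"].notna()
        c_ok = cox["p"].notna()
        pooled = np.concatenate(
            [group_tab.loc[g_ok, "p"].to_numpy(), cox.loc[c_ok, "p"].to_numpy()]
        )
        if pooled.size:
            q = fdr_adjust(pooled)
            n_g = int(g_ok.sum())
            if attach_group:
                group_tab["q"] = np.nan
                group_tab.loc[g_ok, "q"] = q[:n_g]
            cox["q"] = np.nan
            cox.loc[c_ok, "q"] = q[n_g:]
    return {"group": group_tab, "chisq": chis, "cox_ci": cox_ci,
            "cox_pdd": cox_pdd}
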