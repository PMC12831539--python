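"""Standardized regression-based (SRB) practice-effect scoring.

The normative model for each test is an ordinary least-squares regression,
fitted on healthy-control (HC) data, predicting the one-year follow-up score
from the baseline score, age, sex, education, and retest interval:

    followup ~ 1 + baseline + age + sex + education + interval

A subject's SRB z-score is (observed follow-up - predicted follow-up) divided
by the residual SD of the normative fit.  It measures whether the subject
improved more (positive) or less (negative) than demographically comparable
controls retested over the same interval — i.e. the size of their practice
effect relative to the normative expectation.

z-scores for the Trail Making tests are sign-reversed ("oriented") so that on
every test positive means more improvement than expected.  Oriented z-scores
are trichotomized at +/-1.645 (the 5% tails of the standard normal) into
decline / no change / improvement, and a composite practice effect is the
mean of the oriented z-scores of six designated tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .battery import BATTERY, COMPOSITE_MEMBERS, TEST_NAMES, get_test

#: predictor columns of the normative regression, in design-matrix order
PREDICTORS = ("baseline", "age", "sex", "education", "interval")

#: two-sided reliable-change threshold (5% normal tails)
RELIABLE_CHANGE_THRESHOLD = 1.645

#: minimum HC sample for a normative fit (6 parameters + 2 residual df)
MIN_FIT_ROWS = 8

#: minimum number of composite members required for a composite score
DEFAULT_MIN_TESTS = 4

CATEGORIES = ("decline", "no_change", "improvement")


class SampleSizeError(ValueError):
    """Too few complete normative rows to fit an SRB equation."""


class DegenerateFitError(ValueError):
    """The normative regression fits the data perfectly (residual SD = 0)."""


class CollinearityError(ValueError):
    """The normative design matrix is rank deficient."""


@dataclass
class SRBModel:
    """A fitted normative prediction equation for one test.

    ``coefficients`` maps each predictor in :data:`PREDICTORS` to its beta
    weight (score units per predictor unit); ``residual_sd`` is the root mean
    squared error with denominator ``df_resid = n_fit - 6``.
    """

    test: str
    intercept: float
    coefficients: Dict[str, float]
    residual_sd: float
    n_fit: int
    df_resid: int = field(default=0)

    def __post_init__(self):
        if self.df_resid == 0:
            self.df_resid = self.n_fit - (len(PREDICTORS) + 1)

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        """Predicted follow-up score for each row (columns = PREDICTORS)."""
        pred = pd.Series(self.intercept, index=rows.index, dtype=float)
        for name in PREDICTORS:
            pred = pred + self.coefficients[name] * rows[name].astype(float)
        return pred

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "residual_sd": self.residual_sd,
            "n_fit": self.n_fit,
            "df_resid": self.df_resid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SRBModel":
        return cls(**{**d, "coefficients": dict(d["coefficients"])})


def battery_change_table(visits: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long visit table into one row per subject with baseline and
    follow-up battery scores.

    Output columns: subject id, group, demographics, retest interval, and
    ``<test>_baseline`` / ``<test>_followup`` per battery test.  Subjects
    without a visit-1 row (no retest) are dropped.
    """
    base = visits[visits["visit_index"] == 0].set_index("subject_id")
    fu = visits[visits["visit_index"] == 1].set_index("subject_id")
    common = base.index.intersection(fu.index)
    out = base.loc[
        common, ["group", "age", "sex", "education_years", "retest_interval_months"]
    ].copy()
    for name in TEST_NAMES:
        out[f"{name}_baseline"] = base.loc[common, name]
        out[f"{name}_followup"] = fu.loc[common, name]
    return out.reset_index()


def _design_frame(subjects: pd.DataFrame, test: str) -> pd.DataFrame:
    """Complete-case predictor/outcome frame for one test."""
    frame = pd.DataFrame(
        {
            "baseline": subjects[f"{test}_baseline"],
            "age": subjects["age"],
            "sex": subjects["sex"],
            "education": subjects["education_years"],
            "interval": subjects["retest_interval_months"],
            "followup": subjects[f"{test}_followup"],
        },
        index=subjects.index,
    ).astype(float)
    return frame.dropna()


def fit_srb_model(hc_subjects: pd.DataFrame, test: str) -> SRBModel:
    """Fit the normative SRB equation for one test on HC rows.

    Parameters
    ----------
    hc_subjects : DataFrame
        Per-subject table as produced by :func:`battery_change_table`,
        restricted to the normative (HC) group.  Complete-case per test.
    test : str
        Battery test name.

    Raises
    ------
    SampleSizeError, CollinearityError, DegenerateFitError
    """
    get_test(test)
    data = _design_frame(hc_subjects, test)
    n = len(data)
    if n < MIN_FIT_ROWS:
        raise SampleSizeError(
            f"{test}: {n} complete normative rows, need >= {MIN_FIT_ROWS}"
        )
    X = sm.add_constant(data[list(PREDICTORS)], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearityError(f"{test}: normative design matrix is rank deficient")
    fit = sm.OLS(data["followup"], X).fit()
    resid_var = float(fit.mse_resid)  # SSR / (n - 6)
    params = fit.params
    if resid_var <= 1e-12 * max(float(data["followup"].var()), 1.0):
        desc = ", ".join(
            [f"intercept={params['const']:g}"]
            + [f"{p}={params[p]:g}" for p in PREDICTORS]
        )
        raise DegenerateFitError(
            f"{test}: perfect normative fit (residual SD = 0); fitted {desc}"
        )
    return SRBModel(
        test=test,
        intercept=float(params["const"]),
        coefficients={p: float(params[p]) for p in PREDICTORS},
        residual_sd=float(np.sqrt(resid_var)),
        n_fit=n,
        df_resid=int(fit.df_resid),
    )


def fit_all_srb_models(
    hc_subjects: pd.DataFrame, tests=TEST_NAMES
) -> Dict[str, SRBModel]:
    """Fit normative equations for every test with enough HC data."""
    return {t: fit_srb_model(hc_subjects, t) for t in tests}


def apply_srb(model: SRBModel, subjects: pd.DataFrame) -> pd.Series:
    """Raw SRB z-scores (observed - predicted) / residual_sd for each subject.

    Subjects missing any predictor or the observed follow-up get NaN (they
    are excluded from this test, not from the battery).
    """
    if model.residual_sd <= 0:
        raise DegenerateFitError(f"{model.test}: model has residual_sd <= 0")
    frame = _design_frame(subjects, model.test)
    z = (frame["followup"] - model.predict(frame)) / model.residual_sd
    return z.reindex(subjects.index)


def orient_z(z_raw, test: str):
    """Orient a raw SRB z-score so positive always means improvement.

    Sign is flipped for lower-is-better tests (TMT-A, TMT-B) and preserved
    otherwise.  Accepts scalars or array-likes.
    """
    return get_test(test).sign * z_raw


def trichotomize(z_oriented, threshold: float = RELIABLE_CHANGE_THRESHOLD):
    """Classify an oriented SRB z into decline / no_change / improvement.

    Decline iff z <= -threshold, improvement iff z >= +threshold, else
    no change (closed symmetric central band).  Vectorized; NaN maps to NaN,
    non-finite scalars raise.
    """
    arr = np.asarray(z_oriented, dtype=float)
    if arr.ndim == 0:
        if not np.isfinite(arr):
            raise ValueError("z must be finite")
        if arr <= -threshold:
            return "decline"
        if arr >= threshold:
            return "improvement"
        return "no_change"
    out = np.where(
        np.isnan(arr),
        None,
        np.where(
            arr <= -threshold,
            "decline",
            np.where(arr >= threshold, "improvement", "no_change"),
        ),
    )
    if np.isinf(arr).any():
        raise ValueError("z must be finite")
    return pd.Series(out, index=getattr(z_oriented, "index", None))


def composite_srb(
    oriented: Mapping[str, float] | pd.DataFrame,
    min_tests: int = DEFAULT_MIN_TESTS,
):
    """Composite practice effect: mean oriented z over the six member tests.

    Requires at least ``min_tests`` members present; otherwise the composite
    is missing (NaN).  Non-member tests never contribute.  Accepts a mapping
    (one subject) or a DataFrame with one oriented-z column per test.
    """
    if isinstance(oriented, pd.DataFrame):
        members = [t for t in COMPOSITE_MEMBERS if t in oriented.columns]
        sub = oriented[members]
        count = sub.notna().sum(axis=1)
        comp = sub.mean(axis=1)
        return comp.where(count >= min_tests)
    vals = [
        oriented[t]
        for t in COMPOSITE_MEMBERS
        if t in oriented and oriented[t] is not None and np.isfinite(oriented[t])
    ]
    if len(vals) < min_tests:
        return float("nan")
    return float(np.mean(vals))


def score_battery(
    subjects: pd.DataFrame,
    models: Mapping[str, SRBModel],
    min_tests: int = DEFAULT_MIN_TESTS,
    threshold: float = RELIABLE_CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Score every subject on every modelled test.

    Returns one row per subject with ``z_raw_<test>``, oriented ``z_<test>``,
    ``cat_<test>`` and the ``composite`` column, alongside group and
    covariates (for downstream group comparisons and Cox models).
    """
    out = subjects[
        ["subject_id", "group", "age", "sex", "education_years",
         "retest_interval_months"]
    ].copy()
    oriented = {}
    for name, model in models.items():
        z_raw = apply_srb(model, subjects)
        z_or = orient_z(z_raw, name)
        out[f"z_raw_{name}"] = z_raw
        out[f"z_{name}"] = z_or
        out[f"cat_{name}"] = trichotomize(z_or, threshold)
        oriented[name] = z_or
    out["composite"] = composite_srb(pd.DataFrame(oriented), min_tests)
    return out


# ---- model persistence ----------------------------------------------------

def save_models(models: Mapping[str, SRBModel], path) -> None:
    """Serialize fitted normative equations to JSON (full float precision)."""
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=1)


def load_models(path) -> Dict[str, SRBModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: SRBModel.from_dict(v) for k, v in raw.items()}
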