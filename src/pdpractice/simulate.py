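"""Seeded synthetic cohort generator.

Generates HC and PD longitudinal visit tables with the statistical structure
the downstream analysis assumes:

* a standardized latent practice ability ``a_i`` (HC mean 0; PD shifted down
  by ``pd_ability_shift``) drives both smaller one-year practice gains in PD
  (through per-test loadings) and a higher progression hazard (through a
  log-linear Weibull frailty), so the practice-effect -> outcome association
  exists by construction with known ground truth;
* the nine-test battery is observed at baseline and at a retest ~12 months
  later (the retest interval varies with the jittered visit timing);
* MoCA is rendered at every retained annual visit from the subject's true
  state sequence (intact until CI onset, impaired until PDD onset, demented
  thereafter), so that with ``moca_noise = 0`` the threshold-based status
  classifier recovers the generative events exactly;
* per-test availability and per-visit retention reproduce the heterogeneous
  subsample sizes and censoring spread of the emulated cohort.

Returned tables are plain :class:`pandas.DataFrame` objects; all randomness
flows from a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .battery import BATTERY, TEST_NAMES
from .config import SimConfig

# adjusted-MoCA rendering bands per true state
_BAND_INTACT = (26, 30)
_BAND_CI = (22, 25)
_BAND_PDD = (10, 21)


def _draw_demographics(n: int, cfg: SimConfig, rng: np.random.Generator):
    d = cfg.demographics
    age = np.clip(rng.normal(d.age_mean, d.age_sd, n), *d.age_range).round(1)
    sex = (rng.random(n) < d.p_male).astype(int)
    edu = np.clip(np.rint(rng.normal(d.edu_mean, d.edu_sd, n)), *d.edu_range)
    return age, sex, edu.astype(int)


def simulate_event_times(
    config: SimConfig, ability: np.ndarray, rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw latent CI and PDD onset times (months) for given latent abilities.

    CI onset follows a Weibull proportional-hazards law with linear predictor
    ``beta_sim * (-ability)``; the PDD onset adds an independent positive
    Weibull gap with its own frailty ``beta_gap * (-ability)``.  Returns
    continuous times; discretization to visit months happens at rendering.
    """
    ability = np.asarray(ability, dtype=float)
    if not np.all(np.isfinite(ability)):
        raise ValueError("ability values must be finite")
    hz = config.hazard
    n = ability.shape[0]
    w_ci = np.exp(hz.beta_sim * (-ability))
    u = rng.random(n)
    t_ci = hz.ci_scale * (-np.log(u) / w_ci) ** (1.0 / hz.ci_shape)
    w_gap = np.exp(hz.beta_gap * (-ability))
    u2 = rng.random(n)
    gap = hz.gap_scale * (-np.log(u2) / w_gap) ** (1.0 / hz.gap_shape)
    return t_ci, t_ci + gap


def render_moca_series(
    ci_time: float,
    pdd_time: float,
    visit_months: np.ndarray,
    rng: np.random.Generator,
    moca_noise: float = 0.0,
) -> np.ndarray:
    """Render adjusted-MoCA values at the given visit months for one subject.

    Values are drawn uniformly within the band of the subject's true state at
    each visit: >= 26 while intact, 22-25 from CI onset, <= 21 from PDD onset.
    With ``moca_noise > 0`` a rounded Gaussian fluctuation is added and the
    result clipped to the instrument range [0, 30].
    """
    if pdd_time < ci_time:
        raise ValueError("invariant violation: PDD onset before CI onset")
    months = np.asarray(visit_months, dtype=float)
    vals = np.empty(months.shape[0], dtype=int)
    for j, m in enumerate(months):
        if m >= pdd_time:
            lo, hi = _BAND_PDD
        elif m >= ci_time:
            lo, hi = _BAND_CI
        else:
            lo, hi = _BAND_INTACT
        vals[j] = rng.integers(lo, hi + 1)
    if moca_noise > 0:
        vals = vals + np.rint(rng.normal(0.0, moca_noise, vals.shape[0])).astype(int)
    return np.clip(vals, 0, 30)


def _render_moca_matrix(cfg, t_ci, t_pdd, months, attended, rng):
    """Vectorized adjusted-MoCA rendering for the whole cohort."""
    n, k = months.shape
    state = np.zeros((n, k), dtype=int)  # 0 intact, 1 CI, 2 PDD
    state[months >= t_ci[:, None]] = 1
    state[months >= t_pdd[:, None]] = 2
    lo = np.choose(state, [_BAND_INTACT[0], _BAND_CI[0], _BAND_PDD[0]])
    hi = np.choose(state, [_BAND_INTACT[1], _BAND_CI[1], _BAND_PDD[1]])
    vals = lo + np.floor(rng.random((n, k)) * (hi - lo + 1)).astype(int)
    if cfg.moca_noise > 0:
        vals = vals + np.rint(rng.normal(0.0, cfg.moca_noise, (n, k))).astype(int)
    vals = np.clip(vals, 0, 30)
    return np.where(attended, vals, -1)


def simulate_cohort(
    config: SimConfig, rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one HC + PD cohort.

    Returns
    -------
    visits : DataFrame
        One row per subject-visit: ``subject_id, group, age, sex,
        education_years, visit_index, visit_month, retest_interval_months,
        moca_raw`` plus one column per battery test (battery scores present
        at visits 0 and 1 only, subject to per-test availability).
    truth : DataFrame
        One row per subject with the latent ability, continuous latent onset
        times (infinite when beyond the subject's follow-up), the observable
        event indicators/months implied by the visit schedule, and the true
        oriented latent practice change ``z_true_<test>`` per test.
    """
    cfg = config.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_hc, n_pd = cfg.n_hc, cfg.n_pd
    n = n_hc + n_pd
    if n == 0:
        raise ConfigErrorEmpty()
    group = np.array(["HC"] * n_hc + ["PD"] * n_pd)
    subject_id = np.array(
        [f"HC{i + 1:04d}" for i in range(n_hc)]
        + [f"PD{i + 1:04d}" for i in range(n_pd)]
    )
    age, sex, edu = _draw_demographics(n, cfg, rng)

    ability = rng.normal(0.0, 1.0, n)
    ability[group == "PD"] -= cfg.pd_ability_shift

    # --- visit schedule with timing jitter and monotone dropout ----------
    nominal = np.asarray(cfg.visit_months, dtype=float)
    k = nominal.shape[0]
    jitter = rng.uniform(-cfg.visit_jitter, cfg.visit_jitter, (n, k))
    jitter[:, 0] = 0.0  # baseline anchors the clock
    months = np.rint(nominal[None, :] + jitter)
    attended = np.ones((n, k), dtype=bool)
    if k > 2:
        keep = rng.random((n, k - 2)) < cfg.retention
        attended[:, 2:] = np.cumprod(keep, axis=1).astype(bool)
    censor_month = np.max(np.where(attended, months, -np.inf), axis=1)

    # --- progression events ----------------------------------------------
    t_ci, t_pdd = simulate_event_times(cfg, ability, rng)
    ci_hit = attended & (months >= t_ci[:, None])
    pdd_hit = attended & (months >= t_pdd[:, None])
    ci_event = ci_hit.any(axis=1)
    pdd_event = pdd_hit.any(axis=1)
    first = lambda hit: np.where(
        hit.any(axis=1), months[np.arange(n), np.argmax(hit, axis=1)], np.nan
    )
    ci_month = first(ci_hit)
    pdd_month = first(pdd_hit)

    moca_adj = _render_moca_matrix(cfg, t_ci, t_pdd, months, attended, rng)
    moca_raw = np.where(moca_adj >= 0, moca_adj - (edu[:, None] <= 12), -1)
    moca_raw = np.clip(moca_raw, -1, 30)

    # --- battery at baseline and year-1 retest ----------------------------
    interval = months[:, 1]  # retest interval in months, ~12 +/- jitter
    is_pd = group == "PD"
    baseline_scores = {}
    followup_scores = {}
    z_true = {}
    d = cfg.demographics
    for name in TEST_NAMES:
        spec = BATTERY[name]
        cal = cfg.battery_calibration[name]
        lam = float(cfg.pd_deficit[name])
        base_mu = np.where(is_pd, cal.base_mean_pd, cal.base_mean_hc)
        base_sd = np.where(is_pd, cal.base_sd_pd, cal.base_sd_hc)
        base = np.rint(rng.normal(base_mu, base_sd))
        lo, hi = spec.score_range
        base = np.clip(base, lo, hi if hi is not None else np.inf)

        eta = np.sqrt(max(1.0 - lam**2, 0.25))
        z = lam * ability + eta * rng.normal(0.0, 1.0, n)
        z_true[name] = z
        intercept = (
            cal.fu_mean_hc
            - cal.baseline_coef * cal.base_mean_hc
            - cal.age_coef * d.age_mean
            - cal.sex_coef * d.p_male
            - cal.edu_coef * d.edu_mean
            - cal.interval_coef * 12.0
        )
        fu = (
            intercept
            + cal.baseline_coef * base
            + cal.age_coef * age
            + cal.sex_coef * sex
            + cal.edu_coef * edu
            + cal.interval_coef * interval
            + spec.sign * cal.resid_sd * z
        )
        fu = np.clip(np.rint(fu), lo, hi if hi is not None else np.inf)

        avail_p = np.where(is_pd, cal.avail_pd, cal.avail_hc)
        observed = rng.random(n) < avail_p
        baseline_scores[name] = np.where(observed, base, np.nan)
        followup_scores[name] = np.where(observed, fu, np.nan)

    # --- assemble long visit table ----------------------------------------
    rows = []
    for j in range(k):
        att = attended[:, j]
        if not att.any():
            continue
        rec = {
            "subject_id": subject_id[att],
            "group": group[att],
            "age": age[att],
            "sex": sex[att],
            "education_years": edu[att],
            "visit_index": j,
            "visit_month": months[att, j].astype(int),
            "retest_interval_months": interval[att].astype(int),
            "moca_raw": moca_raw[att, j],
        }
        for name in TEST_NAMES:
            if j == 0:
                rec[name] = baseline_scores[name][att]
            elif j == 1:
                rec[name] = followup_scores[name][att]
            else:
                rec[name] = np.nan
        rows.append(pd.DataFrame(rec))
    visits = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["subject_id", "visit_index"], kind="mergesort")
        .reset_index(drop=True)
    )

    last = censor_month
    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "ability": ability,
            "t_ci_latent": np.where(t_ci <= last, t_ci, np.inf),
            "t_pdd_latent": np.where(t_pdd <= last, t_pdd, np.inf),
            "ci_event": ci_event,
            "ci_month": ci_month,
            "pdd_event": pdd_event,
            "pdd_month": pdd_month,
            "censor_month": censor_month,
        }
    )
    for name in TEST_NAMES:
        truth[f"z_true_{name}"] = z_true[name]
    return visits, truth


class ConfigErrorEmpty(ValueError):
    """Raised when the configured cohort contains no subjects."""

    def __init__(self):
        super().__init__("configured cohort is empty (n_hc + n_pd == 0)")
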