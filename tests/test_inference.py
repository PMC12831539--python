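"""Inferential battery checked against long-form oracles: Pearson chi-square
summed term by term, a grid-search Cox partial-likelihood maximizer,
brute-force BH step-up, and the hand product-limit estimator."""

import numpy as np
import pandas as pd
import pytest

from pdpractice.inference import (
    NORMAL_REFERENCE,
    center_predictor,
    chisq_change,
    chisq_table,
    compare_groups,
    cumulative_incidence_by_split,
    fdr_adjust,
    fit_cox,
    full_analysis,
)

from oracles import bh_stepup, cox_grid_mle, pearson_longform, product_limit


class TestGroupComparison:
    def test_constant_outcome_gives_zero_beta(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {"group": ["HC"] * 30 + ["PD"] * 30,
             "age": rng.uniform(50, 75, 60).round(1),
             "sex": rng.integers(0, 2, 60),
             "education_years": rng.integers(10, 20, 60),
             "z_sdmt": 0.7}
        )
        res = compare_groups(scores, "sdmt")
        assert res.beta_group == pytest.approx(0.0, abs=1e-12)

    def test_group_absent_not_estimable(self):
        scores = pd.DataFrame(
            {"group": ["PD"] * 10, "age": 60.0, "sex": 1,
             "education_years": 16, "z_bnt": np.random.default_rng(1).normal(size=10)}
        )
        res = compare_groups(scores, "bnt")
        assert not res.estimable and res.reason == "group_absent"

    def test_recovers_known_shift(self):
        """An injected PD deficit of 0.5 z-units with exchangeable
        covariates is recovered by the adjusted model."""
        rng = np.random.default_rng(2)
        n = 4000
        grp = np.array(["HC"] * (n // 2) + ["PD"] * (n // 2))
        z = rng.normal(size=n) - 0.5 * (grp == "PD")
        scores = pd.DataFrame(
            {"group": grp, "age": rng.uniform(45, 80, n),
             "sex": rng.integers(0, 2, n),
             "education_years": rng.integers(8, 20, n), "z_sdmt": z}
        )
        res = compare_groups(scores, "sdmt")
        assert res.beta_group == pytest.approx(-0.5, abs=3 * res.se)
        assert res.p < 1e-10


class TestChiSquare:
    def test_pearson_matches_longform_oracle(self):
        """(31, 69, 0) against the 5/90/5 split: statistic equals the
        term-by-term sum (~145.1) to 1e-9."""
        res = chisq_change({"decline": 31, "no_change": 69, "improvement": 0},
                           mode="normal", test="tmt_a")
        expected = [100 * NORMAL_REFERENCE[c]
                    for c in ("decline", "no_change", "improvement")]
        oracle = pearson_longform([31, 69, 0], expected)
        assert res.statistic == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(145.1, abs=0.05)
        assert res.df == 2

    def test_identical_proportions_give_zero(self):
        res = chisq_change({"decline": 5, "no_change": 90, "improvement": 5},
                           reference={"decline": 10, "no_change": 180,
                                      "improvement": 10}, mode="hc")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_expected_category_not_computable(self):
        """The HC-reference mode cannot handle a category no control
        occupies while PD subjects do (the empty-decline situation)."""
        res = chisq_change({"decline": 31, "no_change": 69, "improvement": 0},
                           reference={"decline": 0, "no_change": 28,
                                      "improvement": 2}, mode="hc")
        assert not res.computable
        assert res.reason == "zero_expected_category"

    def test_category_empty_in_both_dropped_with_reduced_df(self):
        res = chisq_change({"decline": 10, "no_change": 90, "improvement": 0},
                           reference={"decline": 5, "no_change": 95,
                                      "improvement": 0}, mode="hc")
        assert res.df == 1

    def test_table_falls_back_to_normal_mode(self, scored_cohort):
        tab = chisq_table(scored_cohort["scores"], mode="hc")
        fell_back = tab["note"].notna()
        assert (tab.loc[fell_back, "mode"] == "normal").all()
        assert tab["p"].notna().all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_change({"decline": -1, "no_change": 5, "improvement": 0},
                         mode="normal")


def toy_outcomes_scores(durations, events, z):
    n = len(durations)
    ids = [f"S{i}" for i in range(n)]
    outcomes = pd.DataFrame(
        {"subject_id": ids, "ci_event": events, "ci_time": durations,
         "pdd_event": False, "pdd_time": durations,
         "censor_time": durations}
    )
    scores = pd.DataFrame({"subject_id": ids, "z_sdmt": z,
                           "age": 60.0, "sex": 1})
    return outcomes, scores


class TestCox:
    def test_matches_grid_search_partial_likelihood(self):
        """4-subject fixture with distinct times: the fitted log-HR equals
        the dense-grid maximizer of the hand-written partial likelihood."""
        durations = [5.0, 8.0, 11.0, 16.0]
        events = [True, True, True, False]
        x = [1.0, 0.0, 1.0, 0.0]
        outcomes, scores = toy_outcomes_scores(durations, events, x)
        res = fit_cox(outcomes, scores, "sdmt", "ci", covariates=())
        oracle = cox_grid_mle(durations, events, x)
        assert res.log_hr == pytest.approx(oracle, abs=1e-4)

    def test_no_events_not_estimable(self):
        outcomes, scores = toy_outcomes_scores(
            [10.0, 20.0, 30.0], [False, False, False], [0.1, 0.2, 0.3]
        )
        res = fit_cox(outcomes, scores, "sdmt", "ci", covariates=())
        assert not res.estimable and res.reason == "no_events"

    def test_single_event_too_few(self):
        outcomes, scores = toy_outcomes_scores(
            [10.0, 20.0, 30.0], [True, False, False], [0.1, 0.2, 0.3]
        )
        res = fit_cox(outcomes, scores, "sdmt", "ci", covariates=())
        assert res.reason == "too_few_events"

    def test_constant_predictor_not_estimable(self):
        outcomes, scores = toy_outcomes_scores(
            [10.0, 20.0, 30.0, 40.0], [True, True, False, False],
            [0.5, 0.5, 0.5, 0.5]
        )
        res = fit_cox(outcomes, scores, "sdmt", "ci", covariates=())
        assert res.reason == "constant_predictor"

    def test_hazard_ratio_invariant_to_centering(self, scored_cohort):
        """Mean-centering a Cox covariate is a location shift: the HR and
        its confidence interval are unchanged."""
        out, sc = scored_cohort["outcomes"], scored_cohort["scores"]
        plain = fit_cox(out, sc, "composite", "ci", center=False)
        centered = fit_cox(out, sc, "composite", "ci", center=True)
        assert centered.hr == pytest.approx(plain.hr, abs=1e-8)
        assert centered.ci_low == pytest.approx(plain.ci_low, abs=1e-8)
        assert centered.ci_high == pytest.approx(plain.ci_high, abs=1e-8)

    def test_smaller_practice_effects_raise_hazard(self, scored_cohort):
        """At the default calibration the composite HR per z-unit is well
        below 1 for CI (lower practice ability drives conversion)."""
        res = fit_cox(scored_cohort["outcomes"], scored_cohort["scores"],
                      "composite", "ci")
        assert res.estimable
        assert res.ci_high < 1.0

    def test_center_predictor_values(self):
        np.testing.assert_allclose(center_predictor([1.0, 2.0, 3.0]),
                                   [-1.0, 0.0, 1.0])
        already = np.array([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(center_predictor(already), already)
        np.testing.assert_allclose(center_predictor([1.0, 2.0], enabled=False),
                                   [1.0, 2.0])
        with pytest.raises(ValueError):
            center_predictor([np.nan, 1.0])


class TestSchoenfeld:
    def test_ph_test_attached_and_valid(self, scored_cohort):
        res = fit_cox(scored_cohort["outcomes"], scored_cohort["scores"],
                      "composite", "ci")
        assert 0.0 <= res.ph_test_p <= 1.0
        assert set(res.ph_covariate_p) == {"z", "age", "sex"}

    def test_time_varying_effect_detected(self):
        """A hazard effect that flips sign at the median follow-up violates
        proportionality and is flagged by the Schoenfeld test."""
        rng = np.random.default_rng(10)
        rejected = 0
        reps = 40
        for _ in range(reps):
            n = 150
            x = rng.normal(size=n)
            # piecewise-exponential: strong positive effect early,
            # strong negative effect late
            t1 = rng.exponential(1.0 / np.exp(1.5 * x))
            t = np.where(t1 < 1.0, t1,
                         1.0 + rng.exponential(1.0 / np.exp(-1.5 * x)))
            cens = np.full(n, 4.0)
            obs = np.minimum(t, cens)
            ev = t <= cens
            outcomes, scores = toy_outcomes_scores(obs, ev, x)
            res = fit_cox(outcomes, scores, "sdmt", "ci", covariates=())
            if res.ph_covariate_p.get("z", 1.0) < 0.05:
                rejected += 1
        assert rejected / reps > 0.5


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_matches_bruteforce_on_random_arrays(self):
        rng = np.random.default_rng(11)
        for n in (1, 2, 5, 17, 50):
            p = rng.random(n)
            np.testing.assert_allclose(fdr_adjust(p), bh_stepup(p), atol=1e-12)

    def test_q_dominates_p_and_monotone(self):
        rng = np.random.default_rng(12)
        p = rng.random(30)
        q = fdr_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, np.nan])


class TestCumulativeIncidence:
    def test_matches_product_limit_oracle(self):
        durations = [3.0, 5.0, 7.0, 11.0, 13.0, 17.0]
        events = [True, True, False, True, True, False]
        z = [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]  # median split: 3 low, 3 high
        outcomes, scores = toy_outcomes_scores(durations, events, z)
        curves = cumulative_incidence_by_split(outcomes, scores, "sdmt", "ci")
        for half, idx in (("low", slice(0, 3)), ("high", slice(3, 6))):
            t_or, s_or = product_limit(np.asarray(durations)[idx],
                                       np.asarray(events)[idx])
            sub = curves[curves["split"] == half].set_index("time")
            for t, s in zip(t_or, s_or):
                assert sub.loc[t, "cum_incidence"] == pytest.approx(1 - s)

    def test_no_events_flat_zero(self):
        outcomes, scores = toy_outcomes_scores(
            [10.0, 20.0, 30.0, 40.0], [False] * 4, [-1.0, -0.5, 0.5, 1.0]
        )
        curves = cumulative_incidence_by_split(outcomes, scores, "sdmt", "ci")
        assert (curves["cum_incidence"] == 0.0).all()

    def test_low_half_dominates_under_strong_effect(self, scored_cohort):
        curves = cumulative_incidence_by_split(
            scored_cohort["outcomes"], scored_cohort["scores"],
            "composite", "ci"
        )
        grid = np.arange(0, 120, 12, dtype=float)
        interp = {}
        for half in ("low", "high"):
            sub = curves[curves["split"] == half]
            interp[half] = np.interp(grid, sub["time"], sub["cum_incidence"])
        assert (interp["low"] >= interp["high"] - 1e-12).all()
        assert (interp["low"] > interp["high"]).any()


class TestFullAnalysis:
    def test_tables_and_families(self, scored_cohort):
        tabs = full_analysis(scored_cohort["scores"],
                             scored_cohort["outcomes"])
        group, cox_ci, cox_pdd = tabs["group"], tabs["cox_ci"], tabs["cox_pdd"]
        assert len(group) == 10  # nine tests + composite
        assert (group["q"] >= group["p"] - 1e-12).all()
        ok = cox_ci["p"].notna()
        assert (cox_ci.loc[ok, "q"] >= cox_ci.loc[ok, "p"] - 1e-12).all()
        # estimable CI rows have valid intervals
        est = cox_ci[cox_ci["reason"].isna()]
        assert ((est["ci_low"] <= est["hr"]) & (est["hr"] <= est["ci_high"])).all()
        assert (est["hr"] > 0).all()
        # PDD events are scarcer than CI events
        assert cox_pdd["n_events"].max() <= cox_ci["n_events"].max()
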