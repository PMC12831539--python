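# Methods notes

## The measurement model

A practice effect is the part of a retest score not explained by stable
ability and demographics. The standardized regression-based (SRB) approach
operationalizes "expected change" with a normative OLS regression fitted on
healthy controls only:

    followup = b0 + b1·baseline + b2·age + b3·sex + b4·education
               + b5·retest_interval + ε

The SRB z-score, (observed − predicted) / residual SD, is therefore anchored
to the control population: in-sample its mean is exactly 0 (an OLS identity,
asserted to machine precision in the tests) and its sample SD is
sqrt(df_resid / (n − 1)). The residual SD uses denominator n − 6 (six
parameters; the unbiased estimator — the source analysis does not state its
denominator, so the conventional choice is made here and documented).

Orientation: TMT-A and TMT-B are completion times, so their z-scores are
sign-flipped before any downstream use; positive oriented z always means
more improvement than the normative expectation.

Trichotomization uses the 5% normal tails. The published band description
("< −1.645" / "−1.644–1.644" / "> 1.645") leaves the open intervals
(−1.645, −1.644) and (1.644, 1.645) unassigned; this package closes the
bands symmetrically: decline iff z ≤ −1.645, improvement iff z ≥ +1.645.
The constant is configurable.

Composite: the arithmetic mean of the oriented z-scores of LNST, SDMT, SFT,
JoLO, HVLT-R immediate and delayed. How partial batteries were handled
upstream is unstated; here at least 4 of 6 members are required
(`min_tests`, configurable), and missingness is otherwise per-test: a
subject missing the BNT still contributes to every other test.

Sex is coded 0 = female, 1 = male; education is integer years. These codings
are part of the serialized normative equations (JSON, full float precision)
and must match at application time.

## Cognitive status and event times

Raw MoCA is education-corrected (+1 for ≤12 years, capped at the instrument
ceiling of 30 — the cap is this package's choice; the source is silent).
Adjusted ≥26 is intact, ≤25 CI, ≤21 PDD (PDD implies CI for event purposes).
Inclusion requires an intact adjusted baseline MoCA *and* a ~1-year battery
retest.

Event derivation uses a first-crossing rule: onset is the month of the first
visit at or below the cut-off, with no reversion handling — a subject who
dips and recovers still counts from the dip. The alternative "sustained for
k visits" rule is implemented (`sustained_visits`) but defaults to 1, since
a single onset month per subject with no reversion rule is the behaviour the
analysis needs to reproduce. A first crossing straight into the PDD band
sets both events at the same month. Non-converters are censored at their
last attended MoCA visit.

## The synthetic cohort

The generator's job is to produce data with exactly the statistical
structure the analysis assumes, with known ground truth:

* **Latent practice ability** a_i ~ N(0, 1) in HC; PD is shifted down by
  `pd_ability_shift` (default 1 SD).
* **Battery scores.** Baselines are drawn per group from the cohort's
  descriptive means/SDs, rounded and clipped to each test's legal range.
  Follow-up is the normative linear model plus an oriented latent change
  term z* = λ_test·a_i + η·ε with η = sqrt(max(1 − λ², 0.25)). Because the
  HC variance of z* is 1 whenever λ ≤ sqrt(0.75), the PD-vs-HC gap in fitted
  z-units equals λ exactly for all tests except TMT-A/TMT-B, whose large
  loadings (0.95, 1.15) are mildly attenuated by the η floor. The default
  loadings reproduce the published per-test group effects (e.g. SDMT 0.36).
  The generator does **not** inflate PD residual variance, so the very large
  observed PD z-SDs on the TMT tests (~2.1–2.3) are not emulated.
* **Progression.** CI onset follows a Weibull proportional-hazards law with
  frailty exp(β_sim·(−a_i)); PDD onset adds an independent Weibull gap with
  its own frailty. The per-average-subject scale parameters look large
  (3000 and 26000 months) because the lognormal frailty concentrates events
  in low-ability subjects; the *marginal* behaviour is what was calibrated.
* **Schedule.** Annual visits to 132 months with ±1 month uniform timing
  jitter (so the year-1 retest interval varies over 11–13 months and onsets
  land at months like 11 or 25, not only multiples of 12), monotone per-visit
  dropout after year 1 (retention 0.955/visit), and per-test availability
  matching the emulated cohort's heterogeneous subsample sizes.
* **MoCA rendering.** Adjusted scores are drawn uniformly inside the band of
  the subject's true state at each visit (intact 26–30, CI 22–25, PDD
  10–21), then converted back to raw scores by undoing the education
  correction. With `moca_noise = 0` (the default) the threshold classifier
  recovers the generative event record *exactly* — the round trip is a test
  invariant. Noise adds a rounded Gaussian fluctuation and breaks exactness,
  emulating measurement error; it is off by default because the calibration
  targets are defined through the noiseless threshold rules.

**Calibration.** The Weibull and frailty parameters were calibrated once,
against the target marginal outcome mix for the default 547-subject PD arm —
~39% CI conversion, ~10% PDD conversion, median CI onset ≈23 months, median
PDD onset ≈50 months — using replicate simulations, then frozen as the
package defaults (β_sim = 1.8, CI shape 0.85 / scale 3000; β_gap = 2.25, gap
shape 1.0 / scale 26000). The early-loaded onset distribution with only
partial conversion requires both a decreasing-ish baseline hazard and a
strong frailty: a subpopulation of low-ability subjects converts quickly
while the rest rarely convert within follow-up. At these defaults the
achieved values (measured through the full simulate → classify path, 50
replicates) are CI 39.1%, PDD 10.5–10.8%, median CI onset 25 months, median
PDD onset ≈48.5 months.

**What passing tests do and do not show.** The simulator demonstrates that
the pipeline recovers known effects under its own generative assumptions
(linear normative change, proportional hazards, noiseless MoCA state
rendering, missingness completely at random, non-informative dropout). Real
cohorts violate several of these — practice effects may be non-linear in
age, dropout is plausibly informative, MoCA fluctuates — so green tests
validate the *software and statistics*, not the clinical conclusions.

## Inference details

* Group comparisons: OLS with intercept; the PD indicator's coefficient is
  the effect of interest. Exact-zero outcome variance gives beta exactly 0.
* Chi-square: Pearson goodness-of-fit of PD category counts against expected
  counts from a reference distribution. Default reference is the observed HC
  proportions; when an HC category is empty while PD observations exist
  (expected count 0 — exactly the situation that arises for TMT-A when no
  control declines), the HC-reference test is not computable and the table
  falls back to the theoretical normal tails 0.05/0.90/0.05 with a note.
  Both modes are exposed because the two descriptions of the reference in
  the source conflict; neither is asserted as the original computation.
  Categories empty in both groups are dropped with df reduced.
* Cox: `lifelines` partial-likelihood fit with the Efron tie approximation
  (annual visit months produce heavy ties). Wald 95% CIs. Models with zero
  events among complete cases return "n/a" with reason `no_events`
  (mirroring the small-sample BNT/TMT situation for PDD), as do constant
  predictors and fits with fewer than 2 events.
* Schoenfeld check: per-covariate scaled-residual score tests
  (rank-transformed time); the "global" p refers the *sum* of per-covariate
  statistics to chi-square(k). This ignores the covariance between
  statistics and is therefore an approximation to the usual global test —
  adequate as a flag, not a calibrated joint test.
* Linearity: martingale residuals from the fitted model are correlated with
  the squared centered predictor; p < 0.05 flags curvature and the model is
  refitted with the predictor mean-centered. Centering is a location shift,
  so the HR and its CI are invariant (asserted to 1e-8); the flag only
  changes reporting conventions, which is also how the source handled it.
* FDR: Benjamini–Hochberg ("FDR" is all the source specifies). Two families,
  one per outcome, each pooling the group-comparison p-values with that
  outcome's Cox p-values into a single array; the group table reports the
  CI-family q. Chi-squares are adjusted within their own family.
* Median split for the incidence curves: ties go to the low half;
  deterministic. Visualization only.

## Problem sizes for the replication checks

The evaluation routines use 200 replicate cohorts (761 subjects each) for
the deficit-recovery estimate, 50 replicates for the calibration estimates,
and 500 replicates of a reduced no-effect cohort (80 HC / 200 PD over five
years, baseline hazard rescaled so ≈half of null subjects convert) for the
type-I-error and coverage estimates — the reduced cohort keeps the Cox Wald
test in its asymptotic regime (~100 events per replicate) while keeping the
full battery of checks fast on a single CPU. Root seeds split into
per-replicate streams via `numpy.random.SeedSequence.spawn`.

## Known limitations

* PD score variance inflation (conspicuous on the TMT tests in real data) is
  not modelled; group-difference recovery is exact only for loadings
  ≤ sqrt(0.75).
* The latent-ability model is unidimensional; real batteries have
  domain-specific structure, so cross-test correlations here are stronger
  and more uniform than in real cohorts.
* No competing risks (death before CI), no informative dropout, no
  alternate-form equating, no functional-impairment criterion for the
  dementia-level state.
* The global Schoenfeld p is a sum-of-chi-squares approximation (see above).
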