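"""Simulation configuration: cohort sizes, demographics, per-test calibration,
progression-hazard law, and follow-up schedule.

The default configuration emulates the structure of a PPMI-like observational
cohort: ~214 cognitively intact controls (HC) and ~547 de-novo PD subjects,
a nine-test battery at baseline and a ~1-year retest, annual MoCA screening
visits out to 11 years, per-test availability matching the heterogeneous
subsample sizes of such a cohort, and a progression process producing roughly
39% cognitive-impairment (CI) and 10% dementia-level (PDD) conversions with
early-loaded onsets (median CI onset ~23 months, median PDD onset ~50 months).

A single standardized latent "practice ability" per subject drives both the
per-test practice-gain deficit in PD (through per-test loadings) and the
progression hazard (through a log-linear frailty), so the association the
analysis estimates exists by construction with known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .battery import BATTERY, TEST_NAMES


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


@dataclass
class Demographics:
    """Sampling distributions for age (years), sex (0=female, 1=male) and
    education (integer years)."""

    age_mean: float = 61.3
    age_sd: float = 10.2
    age_range: tuple = (29.0, 83.0)
    p_male: float = 0.60
    edu_mean: float = 15.5
    edu_sd: float = 2.8
    edu_range: tuple = (5, 20)


@dataclass
class TestCalibration:
    """Generative calibration for one battery test.

    Baseline scores are drawn per group from a normal distribution, rounded to
    integers and clipped to the legal range.  The one-year follow-up score is
    a linear function of baseline, age, sex, education and retest interval
    plus an oriented latent-change term scaled by ``resid_sd`` (score units).
    ``intercept`` is solved at run time so the HC follow-up mean matches
    ``fu_mean_hc`` at the expected covariate values.
    """

    base_mean_hc: float
    base_sd_hc: float
    fu_mean_hc: float
    fu_sd_hc: float
    base_mean_pd: float
    base_sd_pd: float
    avail_hc: float
    avail_pd: float
    baseline_coef: float = 0.8
    age_coef: float = 0.0
    sex_coef: float = 0.0
    edu_coef: float = 0.0
    interval_coef: float = 0.0
    resid_sd: float = 0.0  # derived in __post_init__ when left at 0

    def __post_init__(self):
        if self.resid_sd <= 0:
            # residual score noise consistent with the follow-up SD given the
            # baseline autocorrelation (floored at 30% of the follow-up SD)
            explained = (self.baseline_coef * self.base_sd_hc) ** 2
            self.resid_sd = max(
                (max(self.fu_sd_hc**2 - explained, 0.0)) ** 0.5,
                0.3 * self.fu_sd_hc,
            )


def _default_battery_calibration() -> dict:
    """Per-test generative calibration matching the descriptive statistics of
    the emulated cohort (HC baseline/follow-up means and SDs; PD baseline
    means; per-test availability = subsample size / group size)."""
    raw = {
        #        hc_b_m  hc_b_sd fu_m   fu_sd  pd_b_m pd_b_sd av_hc      av_pd
        "lnst":     (10.85, 2.59, 10.90, 2.66, 10.81, 2.65, 185 / 214, 435 / 547),
        "bnt":      (55.46, 8.14, 55.06, 9.56, 54.09, 10.88, 30 / 214, 103 / 547),
        "sdmt":     (47.10, 10.26, 47.62, 10.55, 42.36, 9.96, 1.0, 1.0),
        "sft":      (22.16, 5.28, 22.66, 5.19, 21.84, 5.34, 1.0, 546 / 547),
        "jolo":     (13.08, 2.01, 12.65, 2.45, 12.77, 2.17, 185 / 214, 542 / 547),
        "tmt_a":    (28.40, 10.27, 28.13, 5.65, 34.57, 10.92, 30 / 214, 104 / 547),
        "tmt_b":    (56.86, 20.53, 59.90, 15.68, 73.03, 26.79, 30 / 214, 104 / 547),
        "hvlt_imm": (26.25, 4.56, 26.14, 4.70, 25.37, 4.78, 1.0, 546 / 547),
        "hvlt_del": (9.33, 2.34, 9.08, 2.47, 8.86, 2.44, 1.0, 546 / 547),
    }
    out = {}
    for name, (bm, bs, fm, fs, pm, ps, ah, ap) in raw.items():
        sign = BATTERY[name].sign
        out[name] = TestCalibration(
            base_mean_hc=bm, base_sd_hc=bs, fu_mean_hc=fm, fu_sd_hc=fs,
            base_mean_pd=pm, base_sd_pd=ps, avail_hc=ah, avail_pd=ap,
            # mild, plausible covariate effects (score units), oriented so
            # older age predicts worse follow-up performance on every test
            age_coef=-sign * 0.020 * fs,
            sex_coef=sign * 0.10 * fs,
            edu_coef=sign * 0.025 * fs,
            interval_coef=-sign * 0.040 * fs,
        )
    return out


def _default_pd_deficit() -> dict:
    """Per-test loadings of the latent practice ability.

    PD subjects sit one SD lower on the latent ability, so a loading of
    lambda shifts the PD mean oriented SRB z by -lambda (exactly, for
    loadings <= sqrt(0.75); mildly attenuated above that)."""
    return {
        "lnst": 0.20,
        "bnt": -0.11,
        "sdmt": 0.36,
        "sft": 0.13,
        "jolo": 0.00,
        "tmt_a": 0.95,
        "tmt_b": 1.15,
        "hvlt_imm": 0.25,
        "hvlt_del": 0.04,
    }


@dataclass
class HazardConfig:
    """Weibull proportional-hazards law for progression.

    CI onset time T (months) satisfies S(t | a) = exp(-(t/scale)^shape * w)
    with frailty w = exp(beta_sim * (-a)) for latent ability a.  The PDD onset
    is CI onset plus an independent Weibull gap with its own frailty.
    Defaults were calibrated once so the default cohort reproduces the target
    outcome mix (~39% CI, ~10% PDD, onset medians ~23 and ~50 months).
    """

    ci_shape: float = 0.85
    ci_scale: float = 3000.0
    beta_sim: float = 1.8
    gap_shape: float = 1.0
    gap_scale: float = 26000.0
    beta_gap: float = 2.25


@dataclass
class SimConfig:
    """Full simulator configuration; see module docstring."""

    n_hc: int = 214
    n_pd: int = 547
    visit_months: tuple = tuple(range(0, 133, 12))
    demographics: Demographics = field(default_factory=Demographics)
    battery_calibration: dict = field(default_factory=_default_battery_calibration)
    pd_deficit: dict = field(default_factory=_default_pd_deficit)
    pd_ability_shift: float = 1.0  # latent-ability gap between HC and PD (SD units)
    hazard: HazardConfig = field(default_factory=HazardConfig)
    retention: float = 0.955  # per-visit retention probability after year 1
    moca_noise: float = 0.0  # SD of MoCA fluctuation (0 = noiseless rendering)
    visit_jitter: float = 1.0  # half-width (months) of uniform visit-timing jitter
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_hc < 0:
            raise ConfigError("n_hc must be >= 0")
        if self.n_pd < 0:
            raise ConfigError("n_pd must be >= 0")
        vm = tuple(self.visit_months)
        if len(vm) < 2 or vm[0] != 0:
            raise ConfigError("visit_months must start at 0 and contain >= 2 visits")
        if any(b <= a for a, b in zip(vm, vm[1:])):
            raise ConfigError("visit_months must be strictly increasing")
        if not 0.0 <= self.retention <= 1.0:
            raise ConfigError("retention must be a probability in [0, 1]")
        if self.moca_noise < 0:
            raise ConfigError("moca_noise must be >= 0")
        if self.visit_jitter < 0:
            raise ConfigError("visit_jitter must be >= 0")
        for name in TEST_NAMES:
            if name not in self.battery_calibration:
                raise ConfigError(f"battery_calibration missing test {name!r}")
            cal = self.battery_calibration[name]
            if cal.base_sd_hc <= 0 or cal.base_sd_pd <= 0 or cal.resid_sd <= 0:
                raise ConfigError(f"battery_calibration[{name!r}]: SDs must be > 0")
            for fld, v in (("avail_hc", cal.avail_hc), ("avail_pd", cal.avail_pd)):
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(
                        f"battery_calibration[{name!r}].{fld} must be in [0, 1]"
                    )
            if name not in self.pd_deficit:
                raise ConfigError(f"pd_deficit missing test {name!r}")
        hz = self.hazard
        for fld in ("ci_shape", "ci_scale", "gap_shape", "gap_scale"):
            if getattr(hz, fld) <= 0:
                raise ConfigError(f"hazard.{fld} must be > 0")
        dg = self.demographics
        if not 0.0 <= dg.p_male <= 1.0:
            raise ConfigError("demographics.p_male must be in [0, 1]")
        if dg.age_sd <= 0 or dg.edu_sd <= 0:
            raise ConfigError("demographics SDs must be > 0")
        return self

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visit_months"] = list(self.visit_months)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "demographics" in d and isinstance(d["demographics"], dict):
            dem = dict(d["demographics"])
            for k in ("age_range", "edu_range"):
                if k in dem:
                    dem[k] = tuple(dem[k])
            d["demographics"] = Demographics(**dem)
        if "hazard" in d and isinstance(d["hazard"], dict):
            d["hazard"] = HazardConfig(**d["hazard"])
        if "battery_calibration" in d:
            d["battery_calibration"] = {
                k: (TestCalibration(**v) if isinstance(v, dict) else v)
                for k, v in d["battery_calibration"].items()
            }
        if "visit_months" in d:
            d["visit_months"] = tuple(d["visit_months"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a config from YAML or JSON."""
        with open(path) as fh:
            text = fh.read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})


def null_config(**overrides) -> SimConfig:
    """A no-effect configuration: PD and HC are exchangeable.

    All deficit loadings, the PD latent-ability shift, and the hazard frailty
    coefficients are zero, and PD baseline score distributions are set equal
    to the HC ones.  Used for type-I-error and coverage checks.
    """
    cfg = SimConfig(**overrides)
    cfg.pd_deficit = {name: 0.0 for name in TEST_NAMES}
    cfg.pd_ability_shift = 0.0
    cfg.hazard.beta_sim = 0.0
    cfg.hazard.beta_gap = 0.0
    for cal in cfg.battery_calibration.values():
        cal.base_mean_pd = cal.base_mean_hc
        cal.base_sd_pd = cal.base_sd_hc
    return cfg.validate()
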