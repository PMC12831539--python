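import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pdpractice.config import SimConfig
from pdpractice.simulate import simulate_cohort
from pdpractice.srb import battery_change_table, fit_all_srb_models, score_battery
from pdpractice.status import derive_outcomes


def small_config(**overrides) -> SimConfig:
    """A reduced cohort (full battery availability, 5-year follow-up) that
    keeps per-test normative samples comfortably above the fitting minimum."""
    kwargs = {"n_hc": 120, "n_pd": 160,
              "visit_months": tuple(range(0, 61, 12)), **overrides}
    cfg = SimConfig(**kwargs)
    for cal in cfg.battery_calibration.values():
        cal.avail_hc = 1.0
        cal.avail_pd = 1.0
    return cfg.validate()


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default calibration (seed 7)."""
    cfg = SimConfig(seed=7)
    visits, truth = simulate_cohort(cfg)
    return cfg, visits, truth


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """Fitted norms, per-subject scores and PD outcome records for the
    session cohort."""
    cfg, visits, truth = default_cohort
    subjects = battery_change_table(visits)
    models = fit_all_srb_models(subjects[subjects["group"] == "HC"])
    scores = score_battery(subjects, models)
    outcomes = derive_outcomes(visits)
    return {"config": cfg, "visits": visits, "truth": truth,
            "subjects": subjects, "models": models, "scores": scores,
            "outcomes": outcomes}
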