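#!/usr/bin/env python
"""Fit the normative SRB equations on the HC group and score everyone.

For each battery test an OLS model predicts the 1-year follow-up score from
baseline, age, sex, education and retest interval using HC data only; SRB
z-scores, oriented z-scores, change categories and the six-test composite
follow.  Prints the per-group mean z per test (the HC column is zero by
construction — the in-sample OLS identity).
"""

from pathlib import Path

from pdpractice.battery import TEST_NAMES
from pdpractice.pipeline import read_visits, write_table
from pdpractice.srb import (
    battery_change_table,
    fit_all_srb_models,
    save_models,
    score_battery,
)
from pdpractice.status import filter_baseline_intact

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    visits = read_visits(ROOT / "cohort" / "visits.csv")
    included, excluded = filter_baseline_intact(visits)
    print(f"inclusion: {len(included)} subjects kept, {len(excluded)} excluded")
    visits = visits[visits["subject_id"].isin(set(included))]

    subjects = battery_change_table(visits)
    hc = subjects[subjects["group"] == "HC"]
    models = fit_all_srb_models(hc)
    save_models(models, ROOT / "srb_models.json")
    scores = score_battery(subjects, models)
    write_table(scores, ROOT / "scores.csv")

    print(f"{'test':10s} {'n_fit':>5s} {'resid_sd':>8s} "
          f"{'HC mean z':>10s} {'PD mean z':>10s}")
    for t in TEST_NAMES:
        m = models[t]
        hc_z = scores.loc[scores["group"] == "HC", f"z_{t}"].mean()
        pd_z = scores.loc[scores["group"] == "PD", f"z_{t}"].mean()
        print(f"{t:10s} {m.n_fit:5d} {m.residual_sd:8.2f} "
              f"{hc_z:10.2f} {pd_z:10.2f}")
    comp = scores.groupby("group")["composite"].mean()
    print(f"{'composite':10s} {'':5s} {'':8s} "
          f"{comp.get('HC', float('nan')):10.2f} "
          f"{comp.get('PD', float('nan')):10.2f}")
    print(f"wrote {ROOT}/scores.csv and srb_models.json")


if __name__ == "__main__":
    main()
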