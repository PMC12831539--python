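#!/usr/bin/env python
"""Derive CI/PDD events and onset months for the PD group from MoCA.

Applies the education correction and the PD-specific cut-offs (CI <= 25,
PDD <= 21 on the adjusted score), takes the first threshold crossing as the
onset, and censors non-converters at their last MoCA visit.  Prints the
incidence and onset summaries.
"""

from pathlib import Path

from pdpractice.pipeline import read_visits, write_table
from pdpractice.status import derive_outcomes

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    visits = read_visits(ROOT / "cohort" / "visits.csv")
    outcomes = derive_outcomes(visits, group="PD")
    write_table(outcomes, ROOT / "outcomes.csv")

    n = len(outcomes)
    for label, ev, tcol in (("CI", "ci_event", "ci_time"),
                            ("PDD", "pdd_event", "pdd_time")):
        cases = outcomes[outcomes[ev]]
        t = cases[tcol]
        print(f"{label}: {len(cases)}/{n} ({100 * len(cases) / n:.0f}%) "
              f"converted; onset median {t.median():.0f} months "
              f"(IQR {t.quantile(.25):.0f}-{t.quantile(.75):.0f}, "
              f"range {t.min():.0f}-{t.max():.0f})")
    cens = outcomes[~outcomes["ci_event"]]
    print(f"censored: {len(cens)} subjects at median "
          f"{cens['censor_time'].median():.0f} months")
    print(f"wrote {ROOT}/outcomes.csv")


if __name__ == "__main__":
    main()
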