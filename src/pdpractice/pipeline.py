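"""End-to-end pipeline: simulate -> fit norms -> score -> classify -> analyze.

Every stage reads and writes plain CSV so runs diff cleanly; a JSON manifest
records the config snapshot, seed, per-stage row counts, exclusion tallies
and output checksums, making a run reproducible bit-for-bit from its
manifest inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .battery import TEST_NAMES
from .config import SimConfig
from .inference import cumulative_incidence_by_split, full_analysis
from .simulate import simulate_cohort
from .srb import battery_change_table, fit_all_srb_models, save_models, score_battery
from .status import DEFAULT_THRESHOLDS, StatusThresholds, derive_outcomes, \
    filter_baseline_intact

log = logging.getLogger("pdpractice")

MANDATORY_VISIT_COLUMNS = (
    "subject_id", "group", "age", "sex", "education_years",
    "visit_index", "visit_month", "retest_interval_months", "moca_raw",
)


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class PipelineError(RuntimeError):
    """A pipeline stage could not run; the message names the stage."""


def read_visits(path) -> pd.DataFrame:
    """Read a visit CSV, validating the mandatory column dictionary.

    Unknown columns are preserved; empty fields parse as missing.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"visit table missing mandatory column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as UTF-8 CSV with empty fields for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_rngs(seed: int, stages=("simulate",)) -> Dict[str, np.random.Generator]:
    """Derive one independent generator per stochastic stage from a root seed
    via ``numpy.random.SeedSequence.spawn`` (documented splitting rule)."""
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {s: np.random.default_rng(c) for s, c in zip(stages, children)}


def run_pipeline(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    seed: Optional[int] = None,
    thresholds: StatusThresholds = DEFAULT_THRESHOLDS,
    chisq_mode: str = "hc",
) -> dict:
    """Run the full analysis on a freshly simulated cohort.

    Writes visits, latent truth, fitted norms, per-subject scores, outcome
    records, the four inferential tables, median-split cumulative-incidence
    curve coordinates, and a run manifest into ``out_dir``.  Returns the
    manifest as a dict.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_file(config)
    if seed is not None:
        config.seed = int(seed)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "checksums": {},
    }

    def finish_stage(name, **info):
        manifest["stages"][name] = info
        log.info("stage %s: %s", name, info)

    # -- simulate ----------------------------------------------------------
    rng = stage_rngs(config.seed)["simulate"]
    visits, truth = simulate_cohort(config, rng)
    write_table(visits, out / "visits.csv")
    write_table(truth, out / "truth.csv")
    config.to_yaml(out / "config.yaml")
    finish_stage("simulate", n_subjects=int(visits["subject_id"].nunique()),
                 n_rows=len(visits))

    # -- inclusion ---------------------------------------------------------
    included, excluded = filter_baseline_intact(visits, thresholds)
    visits_inc = visits[visits["subject_id"].isin(set(included))]
    finish_stage("inclusion", included=len(included), excluded=len(excluded),
                 exclusion_reasons=excluded["reason"].value_counts().to_dict()
                 if len(excluded) else {})

    # -- fit norms on HC ---------------------------------------------------
    subjects = battery_change_table(visits_inc)
    hc = subjects[subjects["group"] == "HC"]
    if hc.empty:
        raise PipelineError("fit-norms: no HC subjects to fit normative models")
    models = fit_all_srb_models(hc)
    save_models(models, out / "srb_models.json")
    finish_stage("fit_norms", n_hc=len(hc),
                 per_test_n={t: m.n_fit for t, m in models.items()})

    # -- score -------------------------------------------------------------
    scores = score_battery(subjects, models)
    write_table(scores, out / "scores.csv")
    finish_stage("score", n_scored=len(scores))

    # -- classify ----------------------------------------------------------
    if not (visits_inc["group"] == "PD").any():
        raise PipelineError("classify: no PD subjects")
    outcomes = derive_outcomes(visits_inc, thresholds, group="PD")
    write_table(outcomes, out / "outcomes.csv")
    finish_stage("classify", n_pd=len(outcomes),
                 ci_events=int(outcomes["ci_event"].sum()),
                 pdd_events=int(outcomes["pdd_event"].sum()))

    # -- analyze -----------------------------------------------------------
    # first pass uncentered; refit with mean-centering where the martingale
    # linearity probe flags curvature (hazard ratios are location-invariant)
    tables = full_analysis(scores, outcomes, chisq_mode=chisq_mode)
    center_map: dict = {}
    for key in ("cox_ci", "cox_pdd"):
        t = tables[key]
        flagged = t.loc[t["linearity_p"].notna() & (t["linearity_p"] < 0.05),
                        "predictor"]
        for pred in flagged:
            center_map[pred] = True
    if center_map:
        tables = full_analysis(scores, outcomes, chisq_mode=chisq_mode,
                               center_map=center_map)
    write_table(tables["group"], out / "group_comparison.csv")
    write_table(tables["chisq"], out / "chisq_change.csv")
    write_table(tables["cox_ci"], out / "cox_ci.csv")
    write_table(tables["cox_pdd"], out / "cox_pdd.csv")
    curves = []
    for ot in ("ci", "pdd"):
        c = cumulative_incidence_by_split(outcomes, scores, "composite", ot)
        c.insert(0, "outcome", ot)
        curves.append(c)
    write_table(pd.concat(curves, ignore_index=True),
                out / "cumulative_incidence.csv")
    finish_stage(
        "analyze",
        centered_predictors=sorted(center_map),
        fdr_significant={
            "ci_family": int((tables["cox_ci"]["q"] < 0.05).sum()
                             + (tables["group"]["q"] < 0.05).sum()),
            "pdd_family": int((tables["cox_pdd"]["q"] < 0.05).sum()),
        },
    )

    for f in sorted(out.glob("*.csv")):
        manifest["checksums"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
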