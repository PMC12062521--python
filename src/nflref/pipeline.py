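"""End-to-end orchestration: simulate-or-read -> descriptive tables ->
log-linear cut-off -> BCCG centile model -> centile tables -> Z-scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .centiles import DEFAULT_LEVELS, centile_table, cohort_zscores, fit_gamlss
from .cohort import Cohort
from .descriptive import (
    DEFAULT_STRATA,
    StratumDefinition,
    bootstrap_median_ci,
    reference_interval,
    stratified_reference_intervals,
)
from .io import read_cohort_csv, save_models, write_cohort_csv, write_table_csv
from .loglinear import exponentiate_upper_limit, fit_loglinear
from .simulate import SimulationConfig, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs; the single seed drives every
    randomized stage (simulation and bootstrap)."""

    out_dir: Path
    cohort_csv: Optional[Path] = None  # read this file; None -> simulate
    simulation: Optional[SimulationConfig] = None
    strata: Sequence[StratumDefinition] = DEFAULT_STRATA
    z_mult: float = 1.96
    bootstrap_reps: int = 2000
    levels: Sequence[float] = DEFAULT_LEVELS
    table_ages: Sequence[float] = (20, 30, 40, 50, 60)
    edf_mu: int = 3
    edf_sigma: int = 1
    edf_nu: int = 1
    stratify_by_sex: bool = True
    run_gamlss: bool = True
    seed: int = 0


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full reference-value pipeline; returns a summary dict and
    writes tables/models under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed}
    summary: dict = {"seed": config.seed, "outputs": []}

    def emit_csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        write_table_csv(df, path, meta)
        summary["outputs"].append(str(path))

    # --- cohort ---------------------------------------------------------
    if config.cohort_csv is not None:
        cohort, report = _stage("read_cohort")(read_cohort_csv, config.cohort_csv)
        summary["validation"] = {
            "n_read": report.n_read,
            "n_accepted": report.n_accepted,
            "n_rejected": report.n_rejected,
        }
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        if config.simulation is None:
            sim = sim.model_copy(update={"seed": config.seed})
        cohort = _stage("simulate")(generate_cohort, sim)
        meta["config_hash"] = sim.config_hash()
        write_cohort_csv(cohort, out / "cohort.csv", meta)
        summary["outputs"].append(str(out / "cohort.csv"))
    summary["n_subjects"] = cohort.n
    logger.info("cohort ready: n=%d (%s)", cohort.n, cohort.provenance)

    # --- descriptive reference intervals --------------------------------
    intervals, medians = _stage("descriptive")(
        stratified_reference_intervals,
        cohort,
        config.strata,
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    all_vals = cohort.data["snfl_pg_ml"].to_numpy()
    overall_ri = reference_interval(all_vals, "all")
    overall_med = bootstrap_median_ci(all_vals, reps=config.bootstrap_reps, seed=config.seed)
    rows = []
    for ri, med in zip(
        [overall_ri] + intervals, [overall_med] + medians
    ):
        rows.append(
            {
                "label": ri.stratum_label,
                "n": ri.n,
                "median": med.median,
                "ci_low": med.ci_low,
                "ci_high": med.ci_high,
                "p2.5": ri.lower,
                "p97.5": ri.upper,
                "clsi_ok": ri.meets_clsi_min_n,
            }
        )
    emit_csv("reference_intervals.csv", pd.DataFrame(rows))
    summary["reference_intervals"] = rows

    # --- log-linear cut-off ---------------------------------------------
    fit = _stage("loglinear")(fit_loglinear, cohort)
    formula = exponentiate_upper_limit(fit, z_mult=config.z_mult)
    summary["loglinear"] = {
        "intercept": fit.intercept,
        "beta_age": fit.beta_age,
        "beta_female": fit.beta_female,
        "residual_se": fit.residual_se,
        "scale": formula.scale,
        "age_factor": formula.age_factor,
        "female_factor": formula.female_factor,
    }

    # --- GAMLSS centile model -------------------------------------------
    model = None
    if config.run_gamlss:
        model = _stage("gamlss")(
            fit_gamlss,
            cohort,
            edf_mu=config.edf_mu,
            edf_sigma=config.edf_sigma,
            edf_nu=config.edf_nu,
            stratify_by_sex=config.stratify_by_sex,
        )
        ages = np.asarray(config.table_ages, float)
        lo = max(s.age_domain[0] for s in model.strata.values())
        hi = min(s.age_domain[1] for s in model.strata.values())
        ages = ages[(ages >= lo) & (ages <= hi)]
        table = _stage("centiles")(centile_table, model, ages, config.levels)
        emit_csv("centile_table.csv", table)
        zdf, zsummary = _stage("zscores")(cohort_zscores, model, cohort)
        emit_csv(
            "zscores.csv",
            zdf[["subject_id", "age_years", "sex", "snfl_pg_ml", "z", "percentile"]],
        )
        summary["zscore_summary"] = zsummary

    _stage("write_models")(
        save_models,
        out / "models.json",
        centile_model=model,
        loglinear_fit=fit,
        upper_limit=formula,
        meta=meta,
    )
    summary["outputs"].append(str(out / "models.json"))
    return summary
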