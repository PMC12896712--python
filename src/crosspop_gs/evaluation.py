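"""Scoring and orchestration of the scenario x model x replicate grid.

Accuracy is the Pearson correlation between GEBV and TBV on the target
population's validation animals; bias is the regression coefficient of
TBV on GEBV, b = Cov(GEBV, TBV) / Var(GEBV), with its OLS standard
error.  ``run_grid`` replicates the whole pipeline (simulate the three
populations, build scenarios, fit every model) and returns a tidy table
of per-replicate records ready for external statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gsmodels, refset, simpop

log = logging.getLogger(__name__)

__all__ = ["EvaluationRecord", "accuracy", "bias", "run_grid", "summarize"]


@dataclass
class EvaluationRecord:
    scenario: str
    group: str
    model: str
    fraction: float | None
    replicate: int
    accuracy: float
    bias: float
    bias_se: float
    n_validation: int


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between predicted and true breeding values."""
    g = np.asarray(gebv, dtype=float)
    t = np.asarray(tbv, dtype=float)
    if g.size != t.size or g.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.std(g) == 0 or np.std(t) == 0:
        raise ValueError("accuracy undefined for a constant vector")
    return float(np.corrcoef(g, t)[0, 1])


def bias(gebv: np.ndarray, tbv: np.ndarray) -> tuple[float, float]:
    """Dispersion bias: slope of TBV on GEBV, with its OLS standard error.

    b = Cov(GEBV, TBV) / Var(GEBV); b close to 1 means the predictions
    are neither inflated nor deflated.
    """
    g = np.asarray(gebv, dtype=float)
    t = np.asarray(tbv, dtype=float)
    if g.size != t.size or g.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    sxx = float(np.sum((g - g.mean()) ** 2))
    if sxx == 0:
        raise ValueError("bias undefined: zero GEBV variance")
    b = float(np.sum((g - g.mean()) * (t - t.mean())) / sxx)
    resid = t - t.mean() - b * (g - g.mean())
    se = float(np.sqrt(np.sum(resid**2) / (g.size - 2) / sxx))
    return b, se


def _score(sol: gsmodels.MmeSolution, study_a, model: str, scn, rep: int) -> EvaluationRecord:
    tbv = study_a.tbv[study_a.rows_of(sol.validation_ids)]
    r = accuracy(sol.validation_gebv, tbv)
    b, se = bias(sol.validation_gebv, tbv)
    return EvaluationRecord(
        scenario=scn.name, group=scn.group, model=model, fraction=scn.fraction,
        replicate=rep, accuracy=r, bias=b, bias_se=se,
        n_validation=int(sol.validation_ids.size),
    )


def run_grid(config, replicates: int | None = None, master_seed: int | None = None) -> pd.DataFrame:
    """Run the full scenario x model grid over replicate simulations.

    ``config`` is a :class:`crosspop_gs.workflow_io.RunConfig`.  Each
    replicate simulates the three populations with its own derived seed,
    builds all scenarios, fits every requested model and scores accuracy
    and bias on the target validation animals.  A failing stage aborts
    that replicate with a logged reason; remaining replicates continue.
    """
    replicates = config.replicates if replicates is None else replicates
    master_seed = config.master_seed if master_seed is None else master_seed
    vc = gsmodels.VarianceComponents(
        config.trait["h2"] * config.trait["phenotypic_variance"],
        (1 - config.trait["h2"]) * config.trait["phenotypic_variance"],
    )
    records: list[EvaluationRecord] = []
    for rep in range(replicates):
        try:
            studies = simulate_replicate(config, master_seed, rep)
            scenarios = refset.build_scenarios(
                studies["A"], studies["B"], studies["C"],
                fst_threshold=config.analysis["fst_threshold"],
                fractions=tuple(config.analysis["fractions"]),
                aggregate=config.analysis["aggregate"],
                signal_mode=config.analysis["signal_mode"],
                estimator=config.analysis["fst_estimator"],
            )
            opts = {
                "grm_blend": config.analysis["grm_blend"],
                "window_halfwidth": config.analysis["window_halfwidth"],
            }
            if config.analysis["variance_components"] == "reml":
                vc_used = _reml_components(studies["A"], opts["grm_blend"])
            else:
                vc_used = vc
            for scn in scenarios:
                for model in config.analysis["models"]:
                    sol = gsmodels.predict(model, scn, studies, vc_used, opts)
                    records.append(_score(sol, studies["A"], model, scn, rep))
        except Exception:
            log.exception("replicate %d failed; continuing with the rest", rep)
    return pd.DataFrame([r.__dict__ for r in records])


def simulate_replicate(config, master_seed: int, rep: int) -> dict:
    """Simulate the three populations for one replicate (derived seeds).

    The populations branch off a shared ancestral base cohort and share
    one trait architecture (calibrated on the target population's
    founders), so that cross-population prediction is well-posed.
    """
    genome = simpop.build_genome(
        config.genome["n_chromosomes"], config.genome["total_length_cm"],
        config.genome["n_markers"], config.genome["n_qtl"],
        seed=master_seed * 1000 + rep,
    )
    base = simpop.run_historical(
        genome, [tuple(ph) for ph in config.common["hp_phases"]],
        config.common.get("mutation_rate", 2.5e-5),
        seed=[master_seed, rep, 9],
    )
    studies = {}
    arch = None
    for k, label in enumerate(("A", "B", "C")):
        demo = config.demography(label)
        studies[label] = simpop.simulate_population(
            label, genome, demo, seed=[master_seed, rep, k],
            h2=config.trait["h2"],
            phenotypic_variance=config.trait["phenotypic_variance"],
            gamma_shape=config.trait["gamma_shape"],
            fixed_effect_mean=config.trait["fixed_effect_mean"],
            id_offset=k * 10_000_000,
            base=base,
            architecture=arch,
        )
        if arch is None:
            arch = studies[label].architecture
    return studies


def _reml_components(study_a, grm_blend: float) -> gsmodels.VarianceComponents:
    ref = study_a.reference_ids
    rows = study_a.rows_of(ref)
    phen = study_a.phenotypes[rows]
    ok = ~np.isnan(phen)
    M = study_a.genotypes[rows[ok]].astype(float)
    K = gsmodels.vanraden_grm(M, blend_weight=grm_blend).values
    return gsmodels.em_reml(phen[ok], np.ones((ok.sum(), 1)), K)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per (donor, group, fraction, model) cell, Table-2 style."""
    g = results.groupby(["group", "scenario", "model", "fraction"], dropna=False)
    out = g.agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        b_mean=("bias", "mean"),
        b_sd=("bias", "std"),
        se_mean=("bias_se", "mean"),
        n_replicates=("replicate", "nunique"),
    ).reset_index()
    return out
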