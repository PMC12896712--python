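"""Desk-scale parameter-recovery experiments.

Each function re-measures one printed simulation parameter from scratch
by running the simulator and estimators end to end: narrow-sense
heritability via EM-REML under GBLUP, prediction unbiasedness (the
TBV-on-GEBV regression slope), phenotypic variance, the gamma shape of
QTL effect magnitudes, the crossover rate per Morgan, and the phenotype
missingness rate.  Heritability and unbiasedness are measured on
drift-only (selection-disabled) control populations: truncation
selection genuinely depletes the realized additive variance (Bulmer
effect), so the configured parameter is only the estimand of an
unselected cohort.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import gsmodels, refset, simpop, workflow_io
from .evaluation import _reml_components, accuracy, bias

__all__ = [
    "popA_recovery_runs",
    "phenotypic_variance_check",
    "gamma_shape_recovery",
    "recombination_rate_check",
    "missingness_check",
]


def _desk_popA(seed: int, rep: int, selection: bool = False):
    cfg = workflow_io.load_profile("desk")
    genome = simpop.build_genome(
        cfg.genome["n_chromosomes"], cfg.genome["total_length_cm"],
        cfg.genome["n_markers"], cfg.genome["n_qtl"], seed=seed * 1000 + rep,
    )
    base = simpop.run_historical(
        genome, [tuple(p) for p in cfg.common["hp_phases"]],
        cfg.common.get("mutation_rate", 2.5e-5), seed=[seed, rep, 9],
    )
    return cfg, simpop.simulate_population(
        "A", genome, cfg.demography("A"), seed=[seed, rep, 0],
        selection=selection, base=base,
    )


def popA_recovery_runs(seed: int, n_replicates: int = 10) -> dict[str, np.ndarray]:
    """Heritability and unbiasedness recovery on drift-control populations.

    For each replicate: simulate the desk-scale target population
    without selection, fit GBLUP on its two-generation reference with
    the true variance ratio and score the validation generation
    (accuracy r, dispersion slope b), and estimate variance components
    by EM-REML on the reference.  Returns per-replicate arrays of
    ``h2_reml``, ``bias_b`` and ``accuracy_r``.
    """
    h2s, bs, rs = [], [], []
    for rep in range(n_replicates):
        cfg, study = _desk_popA(seed, rep, selection=False)
        scenario = refset.single_population_scenario(study)
        vc = gsmodels.VarianceComponents(
            cfg.trait["h2"] * cfg.trait["phenotypic_variance"],
            (1 - cfg.trait["h2"]) * cfg.trait["phenotypic_variance"],
        )
        sol = gsmodels.predict("gblup", scenario, {"A": study}, vc)
        tbv = study.tbv[study.rows_of(sol.validation_ids)]
        rs.append(accuracy(sol.validation_gebv, tbv))
        bs.append(bias(sol.validation_gebv, tbv)[0])
        h2s.append(_reml_components(study, cfg.analysis["grm_blend"]).h2)
    return {"h2_reml": np.array(h2s), "bias_b": np.array(bs), "accuracy_r": np.array(rs)}


def phenotypic_variance_check(seed: int, n: int = 20_000) -> float:
    """Sample variance of phenotypes under the default trait configuration."""
    cfg = workflow_io.load_profile("desk")
    rng = np.random.default_rng([seed, 2])
    arch = simpop.TraitArchitecture(
        qtl_effects=np.zeros(1), gamma_shape=cfg.trait["gamma_shape"],
        h2=cfg.trait["h2"], phenotypic_variance=cfg.trait["phenotypic_variance"],
        fixed_effect_mean=cfg.trait["fixed_effect_mean"],
    )
    tbv = rng.normal(0.0, np.sqrt(arch.sigma_a2), n)
    y = simpop.simulate_phenotypes(tbv, arch, 0.0, rng)
    return float(np.var(y, ddof=1))


def gamma_shape_recovery(seed: int, n: int = 100_000) -> float:
    """Max-likelihood gamma shape fitted to resampled QTL effect magnitudes."""
    cfg = workflow_io.load_profile("desk")
    rng = np.random.default_rng([seed, 3])
    mags = simpop.sample_effect_magnitudes(n, cfg.trait["gamma_shape"], rng)
    shape, _, _ = stats.gamma.fit(mags, floc=0.0)
    return float(shape)


def recombination_rate_check(seed: int, n_gametes: int = 10_000) -> float:
    """Mean crossover count per gamete on a single 1-Morgan chromosome."""
    genome = simpop.build_genome(1, 100.0, 10, 1, seed=seed)
    rng = np.random.default_rng([seed, 4])
    haps = rng.integers(0, 2, (2, genome.n_loci)).astype(np.uint8)
    total = 0
    for _ in range(n_gametes):
        _, n_x = simpop.sample_gamete(haps, genome, rng, return_crossovers=True)
        total += int(n_x.sum())
    return total / n_gametes


def missingness_check(seed: int, n: int = 10_000) -> float:
    """Fraction (percent) of phenotype records set missing by the simulator."""
    cfg = workflow_io.load_profile("desk")
    rng = np.random.default_rng([seed, 6])
    arch = simpop.TraitArchitecture(
        qtl_effects=np.zeros(1), gamma_shape=cfg.trait["gamma_shape"],
        h2=cfg.trait["h2"], phenotypic_variance=cfg.trait["phenotypic_variance"],
    )
    tbv = rng.normal(0.0, np.sqrt(arch.sigma_a2), n)
    rate = cfg.demography("A").missing_phenotype_rate
    y = simpop.simulate_phenotypes(tbv, arch, rate, rng)
    return float(np.isnan(y).mean() * 100.0)
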