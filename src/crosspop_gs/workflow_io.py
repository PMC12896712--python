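"""Configuration, file formats and the end-to-end pipeline.

Run configurations are YAML documents validated field-for-field against
a fixed schema (unknown keys are rejected).  Genotypes travel as PLINK
text (.ped/.map, alleles coded 1/2, 0 0 = missing, bp derived from cM
via the 1 cM = 1 Mb convention); pedigrees, phenotypes, TBV and QTL
effects as TSV.  Every artifact written by a stage carries provenance
comment lines (stage, config hash, seed).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divergence, evaluation, gsmodels, refset, simpop

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_profile",
    "write_plink",
    "read_plink",
    "write_study",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Raised when a run configuration violates the schema."""


_GENOME_KEYS = {"n_chromosomes", "total_length_cm", "n_markers", "n_qtl"}
_TRAIT_KEYS = {"h2", "phenotypic_variance", "gamma_shape", "fixed_effect_mean"}
_POP_KEYS = {"hp_phases", "recent", "mutation_rate", "missing_phenotype_rate"}
_RECENT_KEYS = {"n_sires", "n_dams", "n_generations", "sire_replacement",
                "dam_replacement", "offspring_per_dam"}
_ANALYSIS_KEYS = {"fst_threshold", "fst_estimator", "fractions", "aggregate",
                  "signal_mode", "models", "variance_components", "grm_blend",
                  "window_halfwidth"}
_COMMON_KEYS = {"hp_phases", "mutation_rate"}
_TOP_KEYS = {"genome", "trait", "common", "populations", "analysis",
             "replicates", "master_seed"}

_ANALYSIS_DEFAULTS = {
    "fst_threshold": 0.1,
    "fst_estimator": "wc",
    "fractions": [0.10, 0.15, 0.20],
    "aggregate": "centroid",
    "signal_mode": "selected",
    "models": ["gblup", "ssgblup", "wgblup"],
    "variance_components": "true_simulated",
    "grm_blend": 0.05,
    "window_halfwidth": 20,
}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    """Validated run configuration; round-trips losslessly through YAML."""

    genome: dict
    trait: dict
    populations: dict
    common: dict = dc_field(default_factory=lambda: {"hp_phases": [[40, 200, 200]]})
    analysis: dict = dc_field(default_factory=dict)
    replicates: int = 5
    master_seed: int = 1

    def __post_init__(self) -> None:
        _check_keys(self.genome, _GENOME_KEYS, "genome")
        _check_keys(self.trait, _TRAIT_KEYS, "trait")
        _check_keys(self.common, _COMMON_KEYS, "common")
        self.trait.setdefault("fixed_effect_mean", 0.0)
        for label, pop in self.populations.items():
            if label not in ("A", "B", "C"):
                raise ConfigError(f"unknown population label {label!r}")
            _check_keys(pop, _POP_KEYS, f"populations.{label}")
            _check_keys(pop["recent"], _RECENT_KEYS, f"populations.{label}.recent")
        for label in ("A", "B", "C"):
            if label not in self.populations:
                raise ConfigError(f"population {label} missing from config")
        _check_keys(self.analysis, _ANALYSIS_KEYS, "analysis")
        merged = dict(_ANALYSIS_DEFAULTS)
        merged.update(self.analysis)
        self.analysis = merged
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        # constructing each DemographyConfig validates the numeric ranges
        for label in ("A", "B", "C"):
            self.demography(label)

    def demography(self, label: str) -> simpop.DemographyConfig:
        pop = self.populations[label]
        return simpop.DemographyConfig(
            hp_phases=[tuple(ph) for ph in pop["hp_phases"]],
            recent=simpop.RecentConfig(**pop["recent"]),
            mutation_rate=pop.get("mutation_rate", 2.5e-5),
            missing_phenotype_rate=pop.get("missing_phenotype_rate", 0.05),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        _check_keys(raw, _TOP_KEYS, "top level")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "genome": self.genome, "trait": self.trait, "common": self.common,
            "populations": self.populations, "analysis": self.analysis,
            "replicates": self.replicates, "master_seed": self.master_seed,
        }

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_profile(name: str) -> RunConfig:
    """Load a shipped profile: ``desk`` (minutes) or ``paper`` (full scale)."""
    ref = resources.files("crosspop_gs") / "profiles" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return RunConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# PLINK text and TSV round-trips
# ---------------------------------------------------------------------------

def write_plink(
    prefix,
    genotypes: np.ndarray,
    ids: np.ndarray,
    genome,
    family: str = "POP",
    phenotypes: np.ndarray | None = None,
) -> None:
    """Write .ped/.map: alleles 1/2, count = number of '2' alleles, 0 0 missing."""
    prefix = Path(prefix)
    G = np.asarray(genotypes)
    m = genome.n_markers
    if G.shape[1] != m:
        raise ValueError("genotype matrix does not match the marker map")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(m):
            cm = genome.marker_pos[j]
            bp = int(round(cm * 1_000_000))
            fh.write(f"{genome.marker_chrom[j]}\tM{j + 1}\t{cm:.6f}\t{bp}\n")
    allele_strings = {-1: "0 0", 0: "1 1", 1: "1 2", 2: "2 2"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(ids):
            phe = "-9"
            if phenotypes is not None and np.isfinite(phenotypes[i]):
                phe = f"{phenotypes[i]:.6f}"
            row = " ".join(allele_strings[int(g)] for g in G[i])
            fh.write(f"{family} {ind} 0 0 0 {phe} {row}\n")


def read_plink(prefix) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read a .ped/.map pair -> (allele-count matrix, ids, map frame).

    Counts are the number of '2' alleles; a 0-coded (missing) genotype
    becomes -1.  Inconsistent line lengths raise with the line number.
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{prefix}.map line {ln}: expected 4 columns")
            map_rows.append((int(parts[0]), parts[1], float(parts[2]), int(parts[3])))
    map_df = pd.DataFrame(map_rows, columns=["chrom", "snp", "cm", "bp"])
    m = len(map_df)
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            a = np.array(parts[6::2]), np.array(parts[7::2])
            missing = (a[0] == "0") | (a[1] == "0")
            count = (a[0] == "2").astype(np.int8) + (a[1] == "2").astype(np.int8)
            rows.append(np.where(missing, -1, count))
    return np.vstack(rows) if rows else np.empty((0, m), np.int8), np.array(ids), map_df


def _provenance_header(stage: str, cfg_hash: str, seed) -> str:
    return f"# stage={stage}\n# config_sha256={cfg_hash}\n# seed={seed}\n"


def _write_tsv(df: pd.DataFrame, path, stage: str, cfg_hash: str, seed) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(stage, cfg_hash, seed))
        df.to_csv(fh, sep="\t", index=False)


def write_study(study, out_dir, cfg_hash: str = "manual", seed="manual") -> None:
    """Export a simulated population: PLINK genotypes + pedigree/phenotype/TBV TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = study.population_label
    gmask = study.genotyped
    write_plink(
        out / f"pop{label}", study.genotypes[gmask], study.ids[gmask],
        study.genome, family=label, phenotypes=study.phenotypes[gmask],
    )
    _write_tsv(study.pedigree, out / f"pop{label}_pedigree.tsv", "simulate", cfg_hash, seed)
    phen = pd.DataFrame({
        "id": study.ids, "y": study.phenotypes,
        "fixed_effect_level": 1, "generation": study.pedigree["generation"],
    })
    _write_tsv(phen, out / f"pop{label}_phenotypes.tsv", "simulate", cfg_hash, seed)
    _write_tsv(pd.DataFrame({"id": study.ids, "tbv": study.tbv}),
               out / f"pop{label}_tbv.tsv", "simulate", cfg_hash, seed)
    if study.architecture is not None:
        eff = pd.DataFrame({
            "qtl_chrom": study.genome.qtl_chrom, "qtl_pos_cm": study.genome.qtl_pos,
            "beta": study.architecture.qtl_effects,
        })
        _write_tsv(eff, out / f"pop{label}_qtl_effects.tsv", "simulate", cfg_hash, seed)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path, out_dir, replicates: int | None = None,
                 master_seed: int | None = None) -> Path:
    """simulate -> fst -> build-refsets -> predict -> evaluate, with artifacts.

    Writes per-population exports for the first replicate, per-SNP Fst
    and LD/PCA diagnostics, the scenario manifest, the tidy results
    table (results.tsv) and the per-cell summary (summary.tsv).
    Returns the artifact directory.
    """
    cfg = RunConfig.from_yaml(config_path)
    if replicates is not None:
        cfg.replicates = replicates
    if master_seed is not None:
        cfg.master_seed = master_seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    t0 = time.time()
    log.info("stage=simulate seed=%s", cfg.master_seed)

    studies = evaluation.simulate_replicate(cfg, cfg.master_seed, 0)
    for study in studies.values():
        write_study(study, out, h, cfg.master_seed)

    fst_frames = []
    for donor in ("B", "C"):
        res = divergence.fst_per_snp(
            studies["A"].genotypes[studies["A"].genotyped],
            studies[donor].genotypes[studies[donor].genotyped],
            estimator=cfg.analysis["fst_estimator"],
        )
        g = studies["A"].genome
        fst_frames.append(pd.DataFrame({
            "pair": f"A-{donor}", "chrom": g.marker_chrom,
            "pos_cm": g.marker_pos, "fst": res.fst, "undefined": res.undefined,
        }))
    _write_tsv(pd.concat(fst_frames), out / "fst_per_snp.tsv", "fst", h, cfg.master_seed)

    ld_frames = []
    for label, study in studies.items():
        prof = divergence.ld_decay(study.genotypes[study.genotyped], study.genome)
        ld_frames.append(pd.DataFrame({
            "pop": label, "bin_center_kb": prof.bin_centers_kb,
            "mean_r2": prof.mean_r2, "pairs": prof.pair_counts,
        }))
    _write_tsv(pd.concat(ld_frames), out / "ld_decay.tsv", "ld-decay", h, cfg.master_seed)

    merged = np.vstack([s.genotypes[s.genotyped] for s in studies.values()])
    labels = np.concatenate([
        np.repeat(label, int(s.genotyped.sum())) for label, s in studies.items()
    ])
    coords = divergence.pca_coords(merged, 2)
    _write_tsv(pd.DataFrame({"pop": labels, "pc1": coords[:, 0], "pc2": coords[:, 1]}),
               out / "pca_scores.tsv", "pca", h, cfg.master_seed)

    scenarios = refset.build_scenarios(
        studies["A"], studies["B"], studies["C"],
        fst_threshold=cfg.analysis["fst_threshold"],
        fractions=tuple(cfg.analysis["fractions"]),
        aggregate=cfg.analysis["aggregate"],
        signal_mode=cfg.analysis["signal_mode"],
        estimator=cfg.analysis["fst_estimator"],
    )
    manifest = pd.DataFrame([{
        "scenario": s.name, "group": s.group, "donor": s.donor,
        "fraction": s.fraction, "n_reference": s.reference_ids.size,
        "n_validation": s.validation_ids.size, "n_snp_subset": s.snp_subset.size,
        "fst_threshold": cfg.analysis["fst_threshold"],
        "aggregate": cfg.analysis["aggregate"],
    } for s in scenarios])
    _write_tsv(manifest, out / "scenario_manifest.tsv", "build-refsets", h, cfg.master_seed)

    results = evaluation.run_grid(cfg)
    _write_tsv(results, out / "results.tsv", "evaluate", h, cfg.master_seed)
    _write_tsv(evaluation.summarize(results), out / "summary.tsv", "evaluate", h, cfg.master_seed)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return out
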