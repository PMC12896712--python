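"""Reference-set construction from Fst-screened genetic distances.

Implements the stratified mixing design: screen highly differentiated
SNPs between the target population (A) and each donor population (B, C),
rank donor individuals by Euclidean genotype distance to the target on
those SNPs, and form "cross" reference sets (target reference plus the
nearest k% of donors) and "signal" reference sets (the selected donors
alone).  Validation is always the target population's final generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .divergence import fst_per_snp, screen_snps

__all__ = [
    "DistanceRanking",
    "ReferenceScenario",
    "distance_to_target",
    "select_similar",
    "build_scenarios",
    "single_population_scenario",
]


@dataclass
class DistanceRanking:
    candidate_ids: np.ndarray
    distances: np.ndarray
    snp_subset: np.ndarray
    target_label: str = "A"

    def __post_init__(self) -> None:
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ReferenceScenario:
    name: str
    group: str                       # "cross", "signal" or "baseline"
    donor: str | None
    fraction: float | None
    reference_ids: np.ndarray
    validation_ids: np.ndarray
    snp_subset: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.reference_ids, self.validation_ids)
        if overlap.size:
            raise ValueError(f"reference/validation leakage: ids {overlap[:5]}...")


def distance_to_target(
    candidate_genotypes: np.ndarray,
    target_genotypes: np.ndarray,
    snp_subset: np.ndarray,
    candidate_ids: np.ndarray | None = None,
    aggregate: str = "centroid",
    target_label: str = "A",
) -> DistanceRanking:
    """Euclidean genotype distance of each candidate to the target population.

    The target is summarized by its per-SNP mean allele-count vector over
    the screened SNP subset (``aggregate="centroid"``, the default);
    ``mean_pair`` ranks by the root of the mean squared distance to every
    target individual and ``min_pair`` by the nearest one.
    """
    subset = np.asarray(snp_subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("empty SNP subset: Fst screening selected no markers")
    C = np.asarray(candidate_genotypes, dtype=float)[:, subset]
    T = np.asarray(target_genotypes, dtype=float)[:, subset]
    if aggregate == "centroid":
        d = np.sqrt(((C - T.mean(axis=0)) ** 2).sum(axis=1))
    elif aggregate == "mean_pair":
        cross = (C**2).sum(1)[:, None] - 2 * C @ T.T + (T**2).sum(1)[None, :]
        d = np.sqrt(np.maximum(cross, 0).mean(axis=1))
    elif aggregate == "min_pair":
        cross = (C**2).sum(1)[:, None] - 2 * C @ T.T + (T**2).sum(1)[None, :]
        d = np.sqrt(np.maximum(cross, 0).min(axis=1))
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    ids = np.arange(C.shape[0]) if candidate_ids is None else np.asarray(candidate_ids)
    return DistanceRanking(ids, d, subset, target_label)


def select_similar(ranking: DistanceRanking, fraction: float) -> np.ndarray:
    """The floor(fraction * n) nearest candidates (minimum one).

    Ties are broken by ascending candidate id so that selection is a
    pure function of the ranking.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = ranking.candidate_ids.size
    if n == 0:
        raise ValueError("empty ranking")
    k = max(1, int(np.floor(fraction * n)))
    order = np.lexsort((ranking.candidate_ids, ranking.distances))
    return ranking.candidate_ids[order[:k]]


def _phenotyped_genotyped_ids(study) -> np.ndarray:
    mask = study.genotyped & ~np.isnan(study.phenotypes)
    return study.ids[mask]


def build_scenarios(
    popA_study,
    popB_study,
    popC_study,
    fst_threshold: float = 0.1,
    fractions: tuple[float, ...] = (0.10, 0.15, 0.20),
    aggregate: str = "centroid",
    signal_mode: str = "selected",
    estimator: str = "wc",
) -> list[ReferenceScenario]:
    """Build the six cross-population and six single-population scenarios.

    For each donor population and fraction: screen SNPs with Fst above
    the threshold between the target's and the donor's genotyped
    cohorts, rank the donor's phenotyped genotyped individuals by
    distance to the target on those SNPs, and emit a cross scenario
    (target reference plus selected donors, named e.g. ``A+10%B``) and a
    signal scenario (selected donors only, ``signal-B-10``;
    ``signal_mode="full"`` uses the whole donor pool instead).
    Validation ids are the target's final genotyped generation in every
    scenario.  A donor whose screening returns no SNPs is skipped with a
    warning.
    """
    studies = {"B": popB_study, "C": popC_study}
    a_ids = set(popA_study.ids.tolist())
    for label, st in studies.items():
        if a_ids & set(st.ids.tolist()):
            raise ValueError(f"id spaces of A and {label} overlap")
    target_geno = popA_study.genotypes[popA_study.genotyped]
    val_ids = popA_study.validation_ids
    ref_a = np.setdiff1d(popA_study.reference_ids, val_ids)
    scenarios: list[ReferenceScenario] = []
    for donor, study in studies.items():
        fst = fst_per_snp(target_geno, study.genotypes[study.genotyped], estimator=estimator)
        subset = screen_snps(fst, fst_threshold)
        if subset.size == 0:
            warnings.warn(f"donor {donor}: no SNPs above Fst {fst_threshold}; scenarios skipped")
            continue
        cand_ids = _phenotyped_genotyped_ids(study)
        cand_geno = study.genotypes[study.rows_of(cand_ids)]
        ranking = distance_to_target(
            cand_geno, target_geno, subset, candidate_ids=cand_ids,
            aggregate=aggregate, target_label=popA_study.population_label,
        )
        for frac in fractions:
            chosen = select_similar(ranking, frac)
            pct = int(round(100 * frac))
            scenarios.append(
                ReferenceScenario(
                    name=f"A+{pct}%{donor}",
                    group="cross",
                    donor=donor,
                    fraction=frac,
                    reference_ids=np.concatenate([ref_a, chosen]),
                    validation_ids=val_ids,
                    snp_subset=subset,
                )
            )
            signal_ref = chosen if signal_mode == "selected" else cand_ids
            scenarios.append(
                ReferenceScenario(
                    name=f"signal-{donor}-{pct}",
                    group="signal",
                    donor=donor,
                    fraction=frac,
                    reference_ids=signal_ref,
                    validation_ids=val_ids,
                    snp_subset=subset,
                )
            )
    return scenarios


def single_population_scenario(study, name: str | None = None) -> ReferenceScenario:
    """Baseline scenario: the population's own reference generation only."""
    val = study.validation_ids
    ref = np.setdiff1d(study.reference_ids, val)
    return ReferenceScenario(
        name=name or f"{study.population_label}-only",
        group="baseline",
        donor=None,
        fraction=None,
        reference_ids=ref,
        validation_ids=val,
    )
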