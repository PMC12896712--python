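"""Forward-in-time simulator for stratified livestock populations.

Simulates three beef-cattle-like populations with distinct demographic
histories: a long historical random-mating phase that establishes
linkage disequilibrium and the allele-frequency spectrum, followed by a
recent phase of truncation selection on pedigree-BLUP EBVs with
breed-specific sire/dam replacement rates.  The quantitative trait is
purely additive: QTL effect magnitudes are gamma-distributed and
rescaled so that the founder cohort has additive variance h2 * Vp.

Everything downstream (differentiation screening, reference-set design,
genomic prediction) consumes the :class:`SimulatedStudy` produced here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import gsmodels

__all__ = [
    "GenomeMap",
    "RecentConfig",
    "DemographyConfig",
    "TraitArchitecture",
    "SimulatedStudy",
    "InvalidConfigError",
    "build_genome",
    "sample_gamete",
    "mutate_gamete",
    "run_historical",
    "assign_trait",
    "sample_effect_magnitudes",
    "compute_tbv",
    "simulate_phenotypes",
    "run_recent",
    "simulate_population",
    "apply_genotyping_noise",
    "BOVINE_AUTOSOME_PROFILE",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its preconditions."""


# Relative sizes of the 29 bovine autosomes (ARS-UCD1.2-like profile,
# longest to shortest).  Only the shape matters: lengths are rescaled to
# the requested total genetic length.
BOVINE_AUTOSOME_PROFILE = np.array(
    [158.5, 136.2, 121.0, 120.8, 120.1, 117.8, 110.7, 113.4, 105.7, 103.3,
     106.0, 87.2, 83.5, 82.4, 85.0, 81.0, 75.2, 66.0, 64.1, 72.0, 69.9,
     60.8, 52.5, 62.7, 42.4, 51.7, 45.9, 45.9, 51.1]
)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeMap:
    """Marker and QTL coordinates on a multi-chromosome genetic map.

    Positions are centimorgans within chromosome; chromosome ids are
    1-based.  Marker and QTL loci are disjoint roles: haplotypes carry
    both, markers are neutral, only QTL enter the trait model.
    """

    chrom_lengths: np.ndarray          # (n_chrom,) cM
    marker_chrom: np.ndarray           # (m,) 1-based chromosome id
    marker_pos: np.ndarray             # (m,) cM, sorted within chromosome
    qtl_chrom: np.ndarray              # (q,)
    qtl_pos: np.ndarray                # (q,)

    # derived locus layout, filled in __post_init__
    n_loci: int = field(init=False)
    marker_cols: np.ndarray = field(init=False)   # column of each marker in the haplotype
    qtl_cols: np.ndarray = field(init=False)
    _locus_genome_pos: np.ndarray = field(init=False, repr=False)
    _locus_chrom0: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        for name in ("marker_chrom", "qtl_chrom"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("marker_pos", "qtl_pos"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        offsets = np.concatenate([[0.0], np.cumsum(self.chrom_lengths)])
        chrom = np.concatenate([self.marker_chrom, self.qtl_chrom])
        pos = np.concatenate([self.marker_pos, self.qtl_pos])
        if np.any(pos < 0) or np.any(pos > self.chrom_lengths[chrom - 1] + 1e-9):
            raise InvalidConfigError("locus position outside its chromosome")
        gpos = offsets[chrom - 1] + pos
        order = np.argsort(gpos, kind="stable")
        self._locus_genome_pos = gpos[order]
        self._locus_chrom0 = (chrom - 1)[order]
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        m = self.marker_chrom.size
        self.marker_cols = inv[:m]
        self.qtl_cols = inv[m:]
        self.n_loci = int(pos.size)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom_lengths.size)

    @property
    def n_markers(self) -> int:
        return int(self.marker_chrom.size)

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_chrom.size)

    @property
    def total_length(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def chrom_offsets(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.chrom_lengths)])


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items by ``weights``."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(np.int64)
    rem = total - base.sum()
    if rem > 0:
        frac = quota - base
        top = np.argsort(-frac, kind="stable")[:rem]
        base[top] += 1
    return base


def build_genome(
    n_chromosomes: int,
    total_length_cM: float,
    n_markers: int,
    n_qtl: int,
    seed: int,
) -> GenomeMap:
    """Lay out a genome with uniformly random marker and QTL positions.

    Chromosome lengths follow a bovine-autosome profile when 29
    chromosomes are requested (total rescaled to ``total_length_cM``),
    otherwise chromosomes are equal length.  Locus counts per chromosome
    are proportional to chromosome length (largest-remainder rule) and
    positions are uniform within chromosome.
    """
    if n_chromosomes < 1 or total_length_cM <= 0 or n_markers < 1 or n_qtl < 1:
        raise InvalidConfigError("counts must be >= 1 and total length > 0")
    if n_chromosomes == BOVINE_AUTOSOME_PROFILE.size:
        lengths = BOVINE_AUTOSOME_PROFILE / BOVINE_AUTOSOME_PROFILE.sum() * total_length_cM
    else:
        lengths = np.full(n_chromosomes, total_length_cM / n_chromosomes)
    rng = np.random.default_rng(seed)

    def _place(n: int) -> tuple[np.ndarray, np.ndarray]:
        per_chrom = _apportion(n, lengths)
        chrom = np.repeat(np.arange(1, n_chromosomes + 1), per_chrom)
        pos = np.concatenate(
            [np.sort(rng.uniform(0.0, lengths[c], per_chrom[c])) for c in range(n_chromosomes)]
        )
        return chrom, pos

    marker_chrom, marker_pos = _place(n_markers)
    qtl_chrom, qtl_pos = _place(n_qtl)
    return GenomeMap(lengths, marker_chrom, marker_pos, qtl_chrom, qtl_pos)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def sample_gamete(
    parent_haplotypes: np.ndarray,
    genome: GenomeMap,
    rng: np.random.Generator,
    return_crossovers: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Sample one recombinant gamete from a pair of parental haplotypes.

    Per chromosome the crossover count is Poisson with mean equal to the
    chromosome length in Morgans, crossover positions are uniform, and
    the starting parental strand is a fair coin; parental origin
    alternates at each crossover.  ``parent_haplotypes`` has shape
    ``(2, n_loci)`` in the genome's locus column order.
    """
    lengths_morgan = genome.chrom_lengths / 100.0
    n_x = rng.poisson(lengths_morgan)
    starts = rng.integers(0, 2, genome.n_chromosomes)
    total = int(n_x.sum())
    if total:
        chrom_of_x = np.repeat(np.arange(genome.n_chromosomes), n_x)
        offsets = genome.chrom_offsets
        bp = offsets[chrom_of_x] + rng.uniform(0.0, 1.0, total) * genome.chrom_lengths[chrom_of_x]
        bp.sort()
        n_before = np.searchsorted(bp, genome._locus_genome_pos, side="left")
    else:
        n_before = 0
    origin = (starts[genome._locus_chrom0] + n_before) % 2
    gamete = np.where(origin == 0, parent_haplotypes[0], parent_haplotypes[1])
    if return_crossovers:
        return gamete, n_x
    return gamete


def mutate_gamete(
    haplotype: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply recurrent mutation: each locus toggles allele with prob = rate."""
    if not 0.0 <= mutation_rate < 1.0:
        raise InvalidConfigError("mutation rate must be in [0, 1)")
    if mutation_rate == 0.0:
        return haplotype.copy()
    out = haplotype.copy()
    n_flip = rng.binomial(out.size, mutation_rate)
    if n_flip:
        idx = rng.choice(out.size, size=n_flip, replace=False)
        out[idx] ^= 1
    return out


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class RecentConfig:
    n_sires: int
    n_dams: int
    n_generations: int
    sire_replacement: float
    dam_replacement: float
    offspring_per_dam: int = 1

    def __post_init__(self) -> None:
        if self.n_sires < 1 or self.n_dams < 1 or self.n_generations < 0:
            raise InvalidConfigError("recent-phase sizes must be positive")
        for r in (self.sire_replacement, self.dam_replacement):
            if not 0.0 <= r <= 1.0:
                raise InvalidConfigError("replacement rates must be in [0, 1]")
        if self.offspring_per_dam < 1:
            raise InvalidConfigError("offspring_per_dam must be >= 1")


@dataclass
class DemographyConfig:
    """Historical phases plus recent selection phase of one population."""

    hp_phases: list[tuple[int, int, int]]   # (n_generations, start_size, end_size)
    recent: RecentConfig
    mutation_rate: float = 2.5e-5
    missing_phenotype_rate: float = 0.05

    def __post_init__(self) -> None:
        for ph in self.hp_phases:
            n_gen, start, end = ph
            if n_gen < 0 or start < 2 or end < 2:
                raise InvalidConfigError("phase sizes must be >= 2 and lengths >= 0")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise InvalidConfigError("mutation rate must be in [0, 1)")
        if not 0.0 <= self.missing_phenotype_rate < 1.0:
            raise InvalidConfigError("missing-phenotype rate must be in [0, 1)")


@dataclass
class TraitArchitecture:
    """Additive trait: gamma-magnitude QTL effects scaled to h2 * Vp."""

    qtl_effects: np.ndarray
    gamma_shape: float
    h2: float
    phenotypic_variance: float
    fixed_effect_mean: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise InvalidConfigError("h2 must be in (0, 1)")
        if self.phenotypic_variance <= 0:
            raise InvalidConfigError("phenotypic variance must be > 0")
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)

    @property
    def sigma_a2(self) -> float:
        return self.h2 * self.phenotypic_variance

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.phenotypic_variance

    @property
    def variance_ratio(self) -> float:
        """lambda = sigma_e2 / sigma_a2, the MME shrinkage ratio."""
        return self.sigma_e2 / self.sigma_a2


# ---------------------------------------------------------------------------
# study container
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """One simulated population: pedigree, haplotypes, trait and phenotypes.

    Rows of ``pedigree`` align with the leading axis of ``haplotypes``,
    ``phenotypes`` and ``tbv``.  Ids are integers unique within a study;
    an ``id_offset`` at simulation time makes them globally unique across
    populations.  ``generation`` is 0 for the founder cohort (terminal
    historical generation) and 1..n for recent generations.
    """

    genome: GenomeMap
    population_label: str
    pedigree: pd.DataFrame        # id, sire, dam, sex, generation (0 = unknown parent)
    haplotypes: np.ndarray        # (n, 2, n_loci) uint8
    phenotypes: np.ndarray        # (n,) float; NaN = missing
    tbv: np.ndarray               # (n,) float; NaN before trait assignment
    genotyped: np.ndarray         # (n,) bool
    architecture: TraitArchitecture | None = None
    monomorphic_markers: np.ndarray | None = None   # flag computed on the founder cohort

    @property
    def n_individuals(self) -> int:
        return int(len(self.pedigree))

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["id"].to_numpy()

    @property
    def genotypes(self) -> np.ndarray:
        """Marker allele counts (n, m) as int8 in {0, 1, 2} (cached)."""
        if "_geno_cache" not in self.__dict__:
            h = self.haplotypes[:, :, self.genome.marker_cols]
            self.__dict__["_geno_cache"] = (h[:, 0, :] + h[:, 1, :]).astype(np.int8)
        return self.__dict__["_geno_cache"]

    @property
    def qtl_genotypes(self) -> np.ndarray:
        h = self.haplotypes[:, :, self.genome.qtl_cols]
        return (h[:, 0, :] + h[:, 1, :]).astype(np.int8)

    def rows_of(self, ids: np.ndarray) -> np.ndarray:
        lookup = pd.Series(np.arange(self.n_individuals), index=self.pedigree["id"])
        return lookup.loc[np.asarray(ids)].to_numpy()

    @property
    def last_generation(self) -> int:
        return int(self.pedigree["generation"].max())

    @property
    def reference_ids(self) -> np.ndarray:
        """Genotyped reference cohort: the three generations before the last."""
        g = self.pedigree["generation"].to_numpy()
        last = self.last_generation
        return self.ids[(g >= last - 3) & (g <= last - 1) & self.genotyped]

    @property
    def validation_ids(self) -> np.ndarray:
        """Genotyped cohort of the final generation (phenotypes masked downstream)."""
        g = self.pedigree["generation"].to_numpy()
        return self.ids[(g == self.last_generation) & self.genotyped]


def _founder_pedigree(n: int, id_offset: int, rng: np.random.Generator) -> pd.DataFrame:
    sexes = np.zeros(n, dtype=np.int64)
    sexes[n // 2:] = 1                      # equal sex ratio: 0 = male, 1 = female
    rng.shuffle(sexes)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1) + id_offset,
            "sire": 0,
            "dam": 0,
            "sex": sexes,
            "generation": 0,
        }
    )


def run_historical(
    genome: GenomeMap,
    hp_phases: Sequence[tuple[int, int, int]],
    mutation_rate: float,
    seed,
    id_offset: int = 0,
    init_size: int | None = None,
    founders: "SimulatedStudy | None" = None,
) -> SimulatedStudy:
    """Random-mating historical phases; returns the terminal cohort.

    Without ``founders``, generation 0 starts every locus at allele
    frequency 0.5 (alleles drawn independently per haplotype); drift,
    recombination and recurrent mutation then shape the spectrum.  With
    ``founders``, the phases continue from an existing cohort — this is
    how diverging populations are branched off a shared ancestral base.
    Within a phase the census size interpolates linearly from start to
    end; mating is random with an equal sex ratio, no selection and no
    migration.  Only the final generation is retained (as unrelated
    founders).
    """
    rng = np.random.default_rng(seed)
    phases = list(hp_phases)
    if founders is not None:
        haps = founders.haplotypes
        size0 = haps.shape[0]
    else:
        size0 = int(phases[0][1]) if phases else int(init_size or 100)
        if size0 < 2:
            raise InvalidConfigError("initial historical size must be >= 2")
        haps = (rng.random((size0, 2, genome.n_loci)) < 0.5).astype(np.uint8)
    sexes = np.zeros(size0, dtype=np.int64)
    sexes[size0 // 2:] = 1
    rng.shuffle(sexes)
    for (n_gen, start, end) in phases:
        if n_gen == 0:
            continue
        sizes = np.rint(np.linspace(start, end, n_gen + 1)[1:]).astype(int)
        for size in sizes:
            males = np.flatnonzero(sexes == 0)
            females = np.flatnonzero(sexes == 1)
            if males.size == 0 or females.size == 0:
                raise InvalidConfigError("historical generation lost one sex entirely")
            sires = rng.choice(males, size)
            dams = rng.choice(females, size)
            new = np.empty((size, 2, genome.n_loci), dtype=np.uint8)
            for k in range(size):
                new[k, 0] = mutate_gamete(sample_gamete(haps[sires[k]], genome, rng), mutation_rate, rng)
                new[k, 1] = mutate_gamete(sample_gamete(haps[dams[k]], genome, rng), mutation_rate, rng)
            haps = new
            sexes = np.zeros(size, dtype=np.int64)
            sexes[size // 2:] = 1
            rng.shuffle(sexes)
    n = haps.shape[0]
    ped = _founder_pedigree(n, id_offset, rng)
    ped["sex"] = sexes
    geno = haps[:, :, genome.marker_cols].sum(axis=1)
    freq = geno.mean(axis=0) / 2.0
    mono = (freq <= 0.0) | (freq >= 1.0)
    return SimulatedStudy(
        genome=genome,
        population_label="HP",
        pedigree=ped,
        haplotypes=haps,
        phenotypes=np.full(n, np.nan),
        tbv=np.full(n, np.nan),
        genotyped=np.zeros(n, dtype=bool),
        monomorphic_markers=mono,
    )


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def sample_effect_magnitudes(n: int, gamma_shape: float, rng: np.random.Generator) -> np.ndarray:
    """Raw (unscaled) QTL effect magnitudes: Gamma(shape, scale=1)."""
    if gamma_shape <= 0:
        raise InvalidConfigError("gamma shape must be > 0")
    return rng.gamma(gamma_shape, 1.0, n)


def assign_trait(
    genome: GenomeMap,
    founder_qtl_genotypes: np.ndarray,
    gamma_shape: float,
    h2: float,
    phenotypic_variance: float,
    rng: np.random.Generator,
    fixed_effect_mean: float = 0.0,
) -> TraitArchitecture:
    """Draw signed gamma QTL effects and rescale to the target variance.

    Magnitudes are Gamma(shape, 1), signs are fair coins, and a single
    multiplicative constant sets Var(TBV) over the founder cohort to
    exactly h2 * phenotypic_variance, so the combined QTL effects fully
    explain the additive variance.
    """
    Q = np.asarray(founder_qtl_genotypes, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != genome.n_qtl:
        raise InvalidConfigError("founder QTL genotype matrix does not match the genome")
    if not np.any(Q.max(axis=0) != Q.min(axis=0)):
        raise InvalidConfigError("all QTL monomorphic in the founder cohort: cannot scale effects")
    mags = sample_effect_magnitudes(genome.n_qtl, gamma_shape, rng)
    signs = rng.choice([-1.0, 1.0], genome.n_qtl)
    beta = mags * signs
    raw_var = np.var(Q @ beta)
    if raw_var <= 1e-30:
        raise InvalidConfigError("founder TBV variance is zero: cannot scale effects")
    beta *= np.sqrt(h2 * phenotypic_variance / raw_var)
    return TraitArchitecture(beta, gamma_shape, h2, phenotypic_variance, fixed_effect_mean)


def compute_tbv(qtl_genotypes: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """True breeding values: TBV_k = sum_j beta_j * Q_kj."""
    Q = np.asarray(qtl_genotypes, dtype=float)
    beta = np.asarray(effects, dtype=float)
    if Q.shape[1] != beta.size:
        raise ValueError(f"QTL matrix has {Q.shape[1]} columns but {beta.size} effects given")
    return Q @ beta


def simulate_phenotypes(
    tbv: np.ndarray,
    architecture: TraitArchitecture,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """y_i = mu + TBV_i + e_i with e ~ N(0, sigma_e2); NaN marks missing."""
    tbv = np.asarray(tbv, dtype=float)
    y = architecture.fixed_effect_mean + tbv
    if architecture.sigma_e2 > 0:
        y = y + rng.normal(0.0, np.sqrt(architecture.sigma_e2), tbv.size)
    if missing_rate > 0:
        y = y.copy()
        y[rng.random(tbv.size) < missing_rate] = np.nan
    return y


# ---------------------------------------------------------------------------
# recent phase: truncation selection on pedigree-BLUP EBVs
# ---------------------------------------------------------------------------

def _pedigree_ebv(
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    phenotypes: np.ndarray,
    variance_ratio: float,
) -> np.ndarray:
    """Pedigree BLUP EBVs for all animals (A-inverse mixed-model equations)."""
    n = sire_idx.size
    a_inv = gsmodels.a_inverse_from_arrays(sire_idx, dam_idx)
    obs = np.flatnonzero(~np.isnan(phenotypes))
    y = phenotypes[obs]
    X = np.ones((obs.size, 1))
    from scipy import sparse

    Z = sparse.csr_matrix((np.ones(obs.size), (np.arange(obs.size), obs)), shape=(obs.size, n))
    sol = gsmodels.solve_mme(y, X, Z, a_inv, variance_ratio, model_tag="PBLUP")
    return sol.u


def run_recent(
    founders: SimulatedStudy,
    demography: DemographyConfig,
    architecture: TraitArchitecture,
    genome: GenomeMap,
    seed,
    selection: bool = True,
    population_label: str = "A",
) -> SimulatedStudy:
    """Recent generations under EBV truncation selection.

    Each generation every dam produces ``offspring_per_dam`` offspring by
    random sire-dam pairing; pedigree-BLUP EBVs are computed from all
    phenotyped animals recorded so far; the configured fraction of
    breeders with the lowest EBV is culled and replaced by the
    highest-EBV same-sex offspring of the current generation.  The last
    four generations are flagged as genotyped (a three-generation
    reference plus the final validation generation).  With
    ``selection=False`` culling and replacement are random (drift-only
    control).
    """
    rc = demography.recent
    rng = np.random.default_rng(seed)
    n_found = founders.n_individuals
    if n_found < rc.n_sires + rc.n_dams:
        raise InvalidConfigError("not enough founders for the requested breeders")
    sex = founders.pedigree["sex"].to_numpy().copy()
    males = np.flatnonzero(sex == 0)
    females = np.flatnonzero(sex == 1)
    if males.size < rc.n_sires or females.size < rc.n_dams:
        raise InvalidConfigError("not enough founder males/females for the requested breeders")

    id_offset = int(founders.pedigree["id"].iloc[0]) - 1
    haps = [founders.haplotypes]
    sire_idx = np.full(n_found, -1, dtype=np.int64)
    dam_idx = np.full(n_found, -1, dtype=np.int64)
    generation = np.zeros(n_found, dtype=np.int64)
    tbv = compute_tbv(founders.qtl_genotypes, architecture.qtl_effects)
    phen = simulate_phenotypes(tbv, architecture, demography.missing_phenotype_rate, rng)
    tbv = list(tbv)
    phen_list = list(phen)
    sexes = list(sex)

    sires = rng.choice(males, rc.n_sires, replace=False)
    dams = rng.choice(females, rc.n_dams, replace=False)
    n_total = n_found

    for gen in range(1, rc.n_generations + 1):
        n_off = rc.n_dams * rc.offspring_per_dam
        off_dam = np.repeat(dams, rc.offspring_per_dam)
        off_sire = sires[rng.integers(0, sires.size, n_off)]
        all_haps = np.concatenate(haps, axis=0) if len(haps) > 1 else haps[0]
        haps = [all_haps]
        new = np.empty((n_off, 2, genome.n_loci), dtype=np.uint8)
        for k in range(n_off):
            new[k, 0] = mutate_gamete(
                sample_gamete(all_haps[off_sire[k]], genome, rng), demography.mutation_rate, rng
            )
            new[k, 1] = mutate_gamete(
                sample_gamete(all_haps[off_dam[k]], genome, rng), demography.mutation_rate, rng
            )
        haps.append(new)
        off_sex = rng.integers(0, 2, n_off)
        q_off = (new[:, 0, genome.qtl_cols] + new[:, 1, genome.qtl_cols]).astype(float)
        tbv_off = compute_tbv(q_off, architecture.qtl_effects)
        phen_off = simulate_phenotypes(tbv_off, architecture, demography.missing_phenotype_rate, rng)

        sire_idx = np.concatenate([sire_idx, off_sire])
        dam_idx = np.concatenate([dam_idx, off_dam])
        generation = np.concatenate([generation, np.full(n_off, gen)])
        tbv.extend(tbv_off)
        phen_list.extend(phen_off)
        sexes.extend(off_sex)
        off_rows = np.arange(n_total, n_total + n_off)
        n_total += n_off

        if selection:
            ebv = _pedigree_ebv(sire_idx, dam_idx, np.asarray(phen_list), architecture.variance_ratio)
        else:
            ebv = rng.random(n_total)    # random ranking: selection disabled

        for is_dam, current, rate in ((False, sires, rc.sire_replacement), (True, dams, rc.dam_replacement)):
            n_repl = int(round(rate * current.size))
            if n_repl == 0:
                continue
            cand = off_rows[off_sex == (1 if is_dam else 0)]
            if cand.size < n_repl:
                raise InvalidConfigError(
                    f"only {cand.size} candidate {'female' if is_dam else 'male'} offspring "
                    f"for {n_repl} replacements"
                )
            keep = current[np.argsort(-ebv[current], kind="stable")][: current.size - n_repl]
            incoming = cand[np.argsort(-ebv[cand], kind="stable")][:n_repl]
            updated = np.concatenate([keep, incoming])
            if is_dam:
                dams = updated
            else:
                sires = updated

    haps_all = np.concatenate(haps, axis=0) if len(haps) > 1 else haps[0]
    # genotyped cohort: the last four generations (three reference + one validation)
    genotyped = generation >= rc.n_generations - 3
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n_total + 1) + id_offset,
            "sire": np.where(sire_idx >= 0, sire_idx + 1 + id_offset, 0),
            "dam": np.where(dam_idx >= 0, dam_idx + 1 + id_offset, 0),
            "sex": np.asarray(sexes, dtype=np.int64),
            "generation": generation,
        }
    )
    return SimulatedStudy(
        genome=genome,
        population_label=population_label,
        pedigree=ped,
        haplotypes=haps_all,
        phenotypes=np.asarray(phen_list),
        tbv=np.asarray(tbv),
        genotyped=genotyped,
        architecture=architecture,
        monomorphic_markers=founders.monomorphic_markers,
    )


def simulate_population(
    population_label: str,
    genome: GenomeMap,
    demography: DemographyConfig,
    seed,
    h2: float = 0.42,
    phenotypic_variance: float = 1.0,
    gamma_shape: float = 0.4,
    fixed_effect_mean: float = 0.0,
    id_offset: int = 0,
    selection: bool = True,
    base: SimulatedStudy | None = None,
    architecture: TraitArchitecture | None = None,
) -> SimulatedStudy:
    """End-to-end simulation of one population (historical + recent phases).

    ``base`` continues the population-specific historical phases from a
    shared ancestral cohort; ``architecture`` reuses a trait assigned
    elsewhere (populations under comparison must share QTL effects for
    cross-population prediction to be meaningful).  Without it the trait
    is calibrated on this population's own founder cohort.
    """
    rng_seed = seed if isinstance(seed, (list, tuple)) else [int(seed)]
    founders = run_historical(
        genome, demography.hp_phases, demography.mutation_rate,
        list(rng_seed) + [1], id_offset=id_offset, founders=base,
    )
    if architecture is None:
        trait_rng = np.random.default_rng(list(rng_seed) + [2])
        architecture = assign_trait(
            genome, founders.qtl_genotypes, gamma_shape, h2, phenotypic_variance,
            trait_rng, fixed_effect_mean,
        )
    study = run_recent(
        founders, demography, architecture, genome, list(rng_seed) + [3],
        selection=selection, population_label=population_label,
    )
    return study


def apply_genotyping_noise(
    study: SimulatedStudy,
    missing_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Post-hoc genotype masking/errors on the marker matrix (off by default).

    Missing entries are mean-imputed (downstream relationship matrices
    require complete genotypes); errors perturb the allele count by one
    step inside {0, 1, 2}.  Returns a float matrix; the study itself is
    not modified.
    """
    G = study.genotypes.astype(float)
    n, m = G.shape
    if error_rate > 0:
        err = rng.random((n, m)) < error_rate
        shift = np.where(G == 0, 1, np.where(G == 2, -1, rng.choice([-1, 1], (n, m))))
        G = np.where(err, G + shift, G)
    if missing_rate > 0:
        miss = rng.random((n, m)) < missing_rate
        col_mean = np.where(miss, np.nan, G)
        col_mean = np.nanmean(col_mean, axis=0)
        col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
        G = np.where(miss, col_mean[None, :], G)
    return G
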