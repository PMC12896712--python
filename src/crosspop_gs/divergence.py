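"""Population differentiation and structure diagnostics.

Per-SNP fixation index between two populations (Weir & Cockerham 1984
variance-component estimator by default, Hudson as an option), threshold
screening of highly differentiated SNPs, linkage-disequilibrium decay
profiles, and PCA coordinates of genotype matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FstResult",
    "LdDecayProfile",
    "fst_per_snp",
    "screen_snps",
    "ld_decay",
    "pca_coords",
]

CM_PER_MB = 1.0     # map convention: 1 cM = 1 Mb, so kb = cM * 1000


@dataclass
class FstResult:
    fst: np.ndarray                 # per-SNP estimate, aligned to the marker map
    estimator: str                  # "wc" or "hudson"
    n_per_pop: tuple[int, int]
    freqs: np.ndarray               # (2, m) allele frequencies per population
    undefined: np.ndarray           # SNPs monomorphic in both populations (reported as 0)


@dataclass
class LdDecayProfile:
    bin_edges_kb: np.ndarray        # (n_bins + 1,)
    mean_r2: np.ndarray             # (n_bins,), NaN where a bin has no pairs
    pair_counts: np.ndarray
    n_skipped_zero_variance: int = 0

    @property
    def bin_centers_kb(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_kb[:-1] + self.bin_edges_kb[1:])


def _freq_het(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = G.mean(axis=0) / 2.0
    h = (G == 1).mean(axis=0)
    return p, h


def fst_per_snp(
    genotypes_pop1: np.ndarray,
    genotypes_pop2: np.ndarray,
    estimator: str = "wc",
) -> FstResult:
    """Per-SNP two-population Fst from 0/1/2 allele-count matrices.

    The default is the Weir & Cockerham (1984) variance-components
    estimator a / (a + b + c) for diploids without a within-individual
    inbreeding correction; ``estimator="hudson"`` selects the Hudson
    estimator in the Bhatia et al. ratio-of-averages per-SNP form.
    Negative estimates are not clamped.  Loci monomorphic in both
    populations are undefined and reported as 0 with a flag.
    """
    G1 = np.asarray(genotypes_pop1)
    G2 = np.asarray(genotypes_pop2)
    if G1.shape[1] != G2.shape[1]:
        raise ValueError("populations genotyped on different marker sets")
    n1, n2 = G1.shape[0], G2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 individuals")
    p1, h1 = _freq_het(G1)
    p2, h2 = _freq_het(G2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if estimator == "wc":
            r = 2.0
            nbar = (n1 + n2) / 2.0
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
            )
            b = (nbar / (nbar - 1.0)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            denom = a + b + c
            fst = a / denom
        elif estimator == "hudson":
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            denom = p1 * (1 - p2) + p2 * (1 - p1)
            fst = num / denom
        else:
            raise ValueError(f"unknown Fst estimator {estimator!r}")
    undefined = ~np.isfinite(fst)
    fst = np.where(undefined, 0.0, fst)
    return FstResult(fst, estimator, (n1, n2), np.vstack([p1, p2]), undefined)


def screen_snps(fst_result: FstResult, threshold: float) -> np.ndarray:
    """Indices of SNPs with Fst strictly above the threshold, ascending."""
    idx = np.flatnonzero(fst_result.fst > threshold)
    if idx.size == 0:
        warnings.warn(f"no SNPs exceed Fst threshold {threshold}")
    return idx


def ld_decay(
    genotypes: np.ndarray,
    genome,
    max_distance_kb: float = 10_000.0,
    n_bins: int = 20,
) -> LdDecayProfile:
    """Mean r^2 between intra-chromosomal marker pairs, binned by distance.

    r^2 is the squared Pearson correlation of allele counts; distances
    use the 1 cM = 1 Mb convention.  Pairs involving a zero-variance
    marker are skipped and counted.
    """
    G = np.asarray(genotypes, dtype=float)
    edges = np.linspace(0.0, max_distance_kb, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    skipped = 0
    max_cm = max_distance_kb / 1000.0 * CM_PER_MB
    for c in range(1, genome.n_chromosomes + 1):
        cols = np.flatnonzero(genome.marker_chrom == c)
        if cols.size < 2:
            continue
        pos = genome.marker_pos[cols]
        X = G[:, cols]
        sd = X.std(axis=0)
        ok = sd > 0
        skipped += int(np.sum(~ok)) * (cols.size - 1)
        Xo, po = X[:, ok], pos[ok]
        if po.size < 2:
            continue
        R = np.corrcoef(Xo, rowvar=False) ** 2
        iu, ju = np.triu_indices(po.size, k=1)
        d_cm = po[ju] - po[iu]
        within = d_cm <= max_cm
        d_kb = d_cm[within] * 1000.0 / CM_PER_MB
        r2 = R[iu[within], ju[within]]
        which = np.clip(np.searchsorted(edges, d_kb, side="right") - 1, 0, n_bins - 1)
        np.add.at(sums, which, r2)
        np.add.at(counts, which, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayProfile(edges, mean_r2, counts, skipped)


def pca_coords(
    genotypes: np.ndarray,
    n_components: int = 2,
    scale: bool = True,
) -> np.ndarray:
    """Principal-component scores of a genotype matrix.

    Columns are centered and (optionally) scaled by sqrt(2 p (1 - p));
    scores are U * S of the thin SVD, so score vectors are mutually
    orthogonal.  Requests beyond the matrix rank are truncated with a
    warning.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need >= 2 individuals for PCA")
    p = G.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not np.any(keep):
        return np.zeros((G.shape[0], n_components))
    Z = G[:, keep] - 2.0 * p[keep]
    if scale:
        Z = Z / np.sqrt(2.0 * p[keep] * (1.0 - p[keep]))
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if n_components > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; truncating")
        n_components = rank
    return U[:, :n_components] * S[:n_components]
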