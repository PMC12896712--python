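"""Relationship matrices and BLUP machinery for genomic prediction.

Implements the numerator relationship matrix A (tabular method), the
VanRaden genomic relationship matrix G, the single-step H-inverse that
splices G into A on the genotyped block, Henderson's mixed-model
equations for PBLUP/GBLUP/ssGBLUP, SNP-effect ridge BLUP with
per-marker variance weights, the window-average SNP weighting used by
two-step weighted GBLUP, and an EM-REML variance-component estimator.

All solvers are deterministic; no randomness lives in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "RelationshipMatrix",
    "VarianceComponents",
    "MmeSolution",
    "SnpWeightVector",
    "numerator_relationship",
    "tabular_a",
    "a_inverse_from_arrays",
    "vanraden_grm",
    "h_inverse",
    "solve_mme",
    "em_reml",
    "snp_ridge",
    "window_weights",
    "predict",
]


@dataclass
class RelationshipMatrix:
    kind: str                      # "A", "G", "A22" or "Hinv"
    values: np.ndarray
    ids: np.ndarray | None = None
    genotyped_ids: np.ndarray | None = None
    allele_frequencies: np.ndarray | None = None
    blend_weight: float | None = None
    n_dropped_monomorphic: int = 0


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    source: str = "true_simulated"     # or "reml"

    def __post_init__(self) -> None:
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be > 0")

    @property
    def variance_ratio(self) -> float:
        return self.sigma_e2 / self.sigma_a2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class MmeSolution:
    b: np.ndarray                  # fixed-effect estimates
    u: np.ndarray                  # random-effect predictions (EBV / GEBV)
    residual_rel: float            # |C x - rhs| / |rhs| of the normal equations
    model_tag: str = "GBLUP"
    validation_gebv: np.ndarray | None = None
    validation_ids: np.ndarray | None = None


@dataclass
class SnpWeightVector:
    weights: np.ndarray
    window_halfwidth: int
    scaling_constant: float
    source_effects: np.ndarray | None = None


# ---------------------------------------------------------------------------
# pedigree relationship matrices
# ---------------------------------------------------------------------------

def _parent_arrays(pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a (id, sire, dam) pedigree frame to 0-based parent index arrays."""
    ids = pedigree["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = np.array([pos.get(int(s), -1) for s in pedigree["sire"]], dtype=np.int64)
    dam = np.array([pos.get(int(d), -1) for d in pedigree["dam"]], dtype=np.int64)
    rows = np.arange(ids.size)
    if np.any(sire >= rows) or np.any(dam >= rows):
        raise ValueError("pedigree not topologically ordered (or an animal is its own ancestor)")
    return ids, sire, dam


def tabular_a(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """Dense A by the tabular recursion; unknown parents (-1) are unrelated founders."""
    n = sire_idx.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            diag = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            row = 0.5 * A[p, :i]
            diag = 1.0
        else:
            row = np.zeros(i)
            diag = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = diag
    return A


def numerator_relationship(pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A of a topologically ordered pedigree."""
    ids, sire, dam = _parent_arrays(pedigree)
    return RelationshipMatrix("A", tabular_a(sire, dam), ids=ids)


def a_inverse_from_arrays(
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    inbreeding: bool = True,
) -> sparse.csr_matrix:
    """Sparse A-inverse by Henderson's rules (inbreeding-exact by default).

    Inbreeding coefficients are taken from the tabular-A diagonal, so the
    assembled matrix is the exact inverse of :func:`tabular_a`'s output.
    """
    n = sire_idx.size
    if inbreeding:
        F = np.zeros(n)
        A = tabular_a(sire_idx, dam_idx)
        F = np.diag(A) - 1.0
    else:
        F = np.zeros(n)
    Fs = np.where(sire_idx >= 0, F[np.maximum(sire_idx, 0)], 0.0)
    Fd = np.where(dam_idx >= 0, F[np.maximum(dam_idx, 0)], 0.0)
    both = (sire_idx >= 0) & (dam_idx >= 0)
    one = (sire_idx >= 0) ^ (dam_idx >= 0)
    d = np.where(
        both,
        0.5 - 0.25 * (Fs + Fd),
        np.where(one, 0.75 - 0.25 * np.where(sire_idx >= 0, Fs, Fd), 1.0),
    )
    b = 1.0 / d
    rows, cols, vals = [np.arange(n)], [np.arange(n)], [b]
    for parent in (sire_idx, dam_idx):
        known = parent >= 0
        i = np.flatnonzero(known)
        p = parent[known]
        rows += [i, p, p]
        cols += [p, i, p]
        vals += [-0.5 * b[known], -0.5 * b[known], 0.25 * b[known]]
    k = np.flatnonzero(both)
    s, dd = sire_idx[k], dam_idx[k]
    rows += [s, dd]
    cols += [dd, s]
    vals += [0.25 * b[k], 0.25 * b[k]]
    out = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return out.tocsr()


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

def vanraden_grm(
    allele_counts: np.ndarray,
    frequencies: np.ndarray | None = None,
    blend_weight: float = 0.05,
    center: bool = True,
) -> RelationshipMatrix:
    """VanRaden G from 0/1/2 allele counts: G = ZZ' / sum 2 p (1-p).

    Z is the column-centered count matrix (M - 2p); monomorphic SNPs are
    dropped (their 2p(1-p) term is zero).  The returned matrix is
    G* = (1 - w) G + w I, blended toward the identity so that single-step
    assembly can invert it.  ``center=False`` reproduces the uncentered
    cross-product form for comparison.
    """
    M = np.asarray(allele_counts, dtype=float)
    p = M.mean(axis=0) / 2.0 if frequencies is None else np.asarray(frequencies, dtype=float)
    keep = (p > 0.0) & (p < 1.0)
    n_dropped = int((~keep).sum())
    if not np.any(keep):
        raise ValueError("all SNPs monomorphic: cannot build G")
    Mk, pk = M[:, keep], p[keep]
    Z = Mk - 2.0 * pk if center else Mk
    denom = float(np.sum(2.0 * pk * (1.0 - pk)))
    G = Z @ Z.T / denom
    if blend_weight > 0:
        G = (1.0 - blend_weight) * G + blend_weight * np.eye(G.shape[0])
    return RelationshipMatrix(
        "G", G, allele_frequencies=p, blend_weight=blend_weight,
        n_dropped_monomorphic=n_dropped,
    )


def h_inverse(
    A: np.ndarray,
    G_star: np.ndarray,
    genotyped_idx: np.ndarray,
) -> RelationshipMatrix:
    """Single-step H-inverse: A^-1 plus (G*^-1 - A22^-1) on the genotyped block."""
    A = np.asarray(A, dtype=float)
    gi = np.asarray(genotyped_idx, dtype=np.int64)
    Hinv = np.linalg.inv(A)
    if gi.size:
        A22 = A[np.ix_(gi, gi)]
        try:
            G_inv = np.linalg.inv(np.asarray(G_star, dtype=float))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("G* is singular; blend it toward I before inverting") from exc
        try:
            A22_inv = np.linalg.inv(A22)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("A22 is singular") from exc
        Hinv[np.ix_(gi, gi)] += G_inv - A22_inv
    return RelationshipMatrix("Hinv", Hinv, genotyped_ids=gi)


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z,
    K_inverse,
    lam: float,
    model_tag: str = "GBLUP",
) -> MmeSolution:
    """Solve Henderson's MME: [X'X X'Z; Z'X Z'Z + lam K^-1][b; u] = [X'y; Z'y].

    ``Z`` and ``K_inverse`` may be dense or scipy.sparse; a sparse
    K-inverse selects the sparse solver path.  Rank-deficient systems
    fall back to a pseudo-inverse solution with a warning (fixed effects
    then estimable only up to the usual constraints).
    """
    if lam <= 0:
        raise ValueError("variance ratio lambda must be > 0")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    p = X.shape[1]
    sparse_path = sparse.issparse(K_inverse)
    Zs = sparse.csr_matrix(Z) if sparse_path and not sparse.issparse(Z) else Z
    XtX = X.T @ X
    XtZ = (Zs.T @ X).T if sparse.issparse(Zs) else X.T @ Zs
    ZtZ = Zs.T @ Zs
    Xty = X.T @ y
    Zty = Zs.T @ y
    rhs = np.concatenate([Xty, np.asarray(Zty).ravel()])
    if sparse_path:
        C = sparse.bmat(
            [
                [sparse.csr_matrix(XtX), sparse.csr_matrix(XtZ)],
                [sparse.csr_matrix(XtZ.T), ZtZ + lam * K_inverse],
            ],
            format="csc",
        )
        try:
            sol = spsolve(C, rhs)
        except Exception:
            sol = np.linalg.lstsq(C.toarray(), rhs, rcond=None)[0]
            warnings.warn("sparse MME solve failed; used least-squares fallback")
        resid = np.linalg.norm(C @ sol - rhs)
    else:
        Zd = Zs.toarray() if sparse.issparse(Zs) else np.asarray(Zs, dtype=float)
        Kd = np.asarray(K_inverse, dtype=float)
        XtZd = X.T @ Zd
        C = np.block([[XtX, XtZd], [XtZd.T, Zd.T @ Zd + lam * Kd]])
        try:
            sol = np.linalg.solve(C, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("MME coefficient matrix singular; fixed effects not fully estimable")
            sol = np.linalg.pinv(C) @ rhs
        resid = np.linalg.norm(C @ sol - rhs)
    rhs_norm = np.linalg.norm(rhs)
    return MmeSolution(
        b=sol[:p],
        u=sol[p:],
        residual_rel=float(resid / rhs_norm) if rhs_norm > 0 else 0.0,
        model_tag=model_tag,
    )


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    init: tuple[float, float] | None = None,
) -> VarianceComponents:
    """EM-REML for the one-random-effect animal model y = Xb + u + e.

    u ~ N(0, K sigma_a2) with K the relationship matrix over the
    phenotyped animals (Z = I), e ~ N(0, I sigma_e2).  The classic EM
    updates iterate the MME at the current variance ratio:

        sigma_a2 <- (u' K^-1 u + sigma_e2 tr(K^-1 Cuu)) / q
        sigma_e2 <- (y'y - b'X'y - u'Z'y) / (n - rank(X))
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    q = K.shape[0]
    if q != n:
        raise ValueError("em_reml expects one record per random level (Z = I)")
    K_inv = np.linalg.inv(K)
    rank_x = np.linalg.matrix_rank(X)
    vy = float(np.var(y, ddof=1))
    sa2, se2 = init if init is not None else (0.5 * vy, 0.5 * vy)
    XtX, Xty = X.T @ X, X.T @ y
    for _ in range(max_iter):
        lam = se2 / sa2
        C = np.block([[XtX, X.T], [X, np.eye(n) + lam * K_inv]])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ np.concatenate([Xty, y])
        b, u = sol[:p], sol[p:]
        Cuu = Cinv[p:, p:]
        sa2_new = float((u @ K_inv @ u + se2 * np.trace(K_inv @ Cuu)) / q)
        se2_new = float((y @ y - b @ Xty - u @ y) / (n - rank_x))
        done = abs(sa2_new - sa2) < tol * max(sa2, 1e-12) and abs(se2_new - se2) < tol * max(se2, 1e-12)
        sa2, se2 = max(sa2_new, 1e-12), max(se2_new, 1e-12)
        if done:
            break
    return VarianceComponents(sa2, se2, source="reml")


# ---------------------------------------------------------------------------
# SNP-effect ridge BLUP and window weights
# ---------------------------------------------------------------------------

def snp_ridge(
    y: np.ndarray,
    X: np.ndarray | None,
    Z_s: np.ndarray,
    W: np.ndarray,
    variance_components: VarianceComponents,
    sigma_alpha2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP of per-SNP effects under alpha ~ N(0, W sigma_alpha2), e ~ N(0, I sigma_e2).

    Solved in the n-dimensional dual (n animals << m SNPs):
        alpha_hat = sigma_alpha2 W Z' P y,
    with V = Z W Z' sigma_alpha2 + I sigma_e2 and P the usual REML
    projection absorbing the fixed effects.  When W = I and
    sigma_alpha2 = sigma_a2 / sum 2 p q with the same centering as the
    GRM, Z alpha_hat reproduces GBLUP's GEBV exactly (equivalent models).

    Returns ``(alpha_hat, b_hat)``.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z_s, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim == 2:
        W = np.diag(W)
    if np.any(W < 0):
        raise ValueError("SNP weights must be non-negative")
    if not np.any(W > 0):
        raise ValueError("all SNP weights zero: degenerate model")
    sa2 = variance_components.sigma_a2 if sigma_alpha2 is None else sigma_alpha2
    se2 = variance_components.sigma_e2
    n = y.size
    ZW = Z * W[None, :]
    V = sa2 * (ZW @ Z.T) + se2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    if X is None:
        P = Vinv
        b = np.zeros(0)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        XtVinv = X.T @ Vinv
        b = np.linalg.solve(XtVinv @ X, XtVinv @ y)
        P = Vinv - Vinv @ X @ np.linalg.solve(XtVinv @ X, XtVinv)
    alpha = sa2 * W * (Z.T @ (P @ y))
    return alpha, b


def window_weights(
    alpha_hat: np.ndarray,
    S: int,
    marker_chrom: np.ndarray | None = None,
) -> SnpWeightVector:
    """Window-averaged squared-effect SNP weights, scaled to mean 1.

    The raw weight of SNP j is the mean of alpha_k^2 over the window
    [j - S, j + S], truncated at chromosome boundaries (the divisor is
    the number of SNPs actually available).  A single constant C then
    scales the weights so their mean is exactly 1.
    """
    if S < 0:
        raise ValueError("window half-width S must be >= 0")
    a2 = np.asarray(alpha_hat, dtype=float) ** 2
    m = a2.size
    if not np.any(a2 > 0):
        warnings.warn("all SNP effects zero: returning uniform weights")
        return SnpWeightVector(np.ones(m), S, 1.0, np.asarray(alpha_hat, dtype=float))
    chrom = np.zeros(m, dtype=np.int64) if marker_chrom is None else np.asarray(marker_chrom)
    raw = np.empty(m)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        x = a2[idx]
        cs = np.concatenate([[0.0], np.cumsum(x)])
        j = np.arange(x.size)
        lo = np.maximum(j - S, 0)
        hi = np.minimum(j + S, x.size - 1)
        raw[idx] = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)
    C = 1.0 / raw.mean()
    return SnpWeightVector(C * raw, S, C, np.asarray(alpha_hat, dtype=float))


# ---------------------------------------------------------------------------
# scenario-level prediction
# ---------------------------------------------------------------------------

def _bundle_lookup(study_bundle: dict) -> dict[int, tuple[object, int]]:
    table: dict[int, tuple[object, int]] = {}
    for study in study_bundle.values():
        for row, i in enumerate(study.pedigree["id"].to_numpy()):
            table[int(i)] = (study, row)
    return table


def _gather_genotypes(lookup, ids: np.ndarray) -> np.ndarray:
    per_study: dict[int, list] = {}
    studies: dict[int, object] = {}
    order = []
    for k, i in enumerate(ids):
        study, row = lookup[int(i)]
        sid = id(study)
        per_study.setdefault(sid, []).append((k, row))
        studies[sid] = study
    out = None
    for sid, pairs in per_study.items():
        study = studies[sid]
        rows = np.array([r for _, r in pairs])
        ks = np.array([k for k, _ in pairs])
        g = study.genotypes[rows].astype(float)
        if out is None:
            out = np.empty((ids.size, g.shape[1]))
        out[ks] = g
    return out


def _gather_scalar(lookup, ids: np.ndarray, attr: str) -> np.ndarray:
    out = np.empty(ids.size)
    for k, i in enumerate(ids):
        study, row = lookup[int(i)]
        out[k] = getattr(study, attr)[row]
    return out


def _ancestor_closure(study, rows: np.ndarray) -> np.ndarray:
    """Row indices of ``rows`` plus all their pedigree ancestors."""
    ids = study.pedigree["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = study.pedigree["sire"].to_numpy()
    dam = study.pedigree["dam"].to_numpy()
    inset = np.zeros(ids.size, dtype=bool)
    inset[rows] = True
    for k in range(ids.size - 1, -1, -1):      # topological order: one reverse sweep
        if inset[k]:
            for parent in (sire[k], dam[k]):
                if parent:
                    inset[pos[int(parent)]] = True
    return np.flatnonzero(inset)


def predict(
    model: str,
    scenario,
    study_bundle: dict,
    variance_components: VarianceComponents,
    options: dict | None = None,
) -> MmeSolution:
    """Fit a prediction model for one reference scenario.

    ``model`` is one of ``pblup``, ``gblup``, ``ssgblup``, ``wgblup``.
    Training records are the scenario's reference individuals with
    observed phenotypes; GEBVs are returned for the validation ids
    (their phenotypes are never used).  GBLUP/wGBLUP are purely genomic
    over reference + validation genotypes; ssGBLUP additionally uses the
    pedigree-ancestor closure of those animals, with phenotyped
    non-genotyped ancestors of the reference contributing records.

    Options: ``grm_blend`` (default 0.05), ``window_halfwidth`` (default
    20), ``center`` (default True), ``force_identity_weights`` (wGBLUP
    skips the weighting step).
    """
    opts = {"grm_blend": 0.05, "window_halfwidth": 20, "center": True,
            "force_identity_weights": False}
    opts.update(options or {})
    model = model.lower()
    lookup = _bundle_lookup(study_bundle)
    ref_ids = np.asarray(scenario.reference_ids)
    val_ids = np.asarray(scenario.validation_ids)
    for i in np.concatenate([ref_ids, val_ids]):
        if int(i) not in lookup:
            raise KeyError(f"scenario id {i} not present in the study bundle")
    lam = variance_components.variance_ratio

    ref_phen = _gather_scalar(lookup, ref_ids, "phenotypes")
    obs_mask = ~np.isnan(ref_phen)
    train_ids = ref_ids[obs_mask]
    y = ref_phen[obs_mask]

    if model in ("gblup", "wgblup"):
        all_ids = np.concatenate([ref_ids, val_ids])
        M = _gather_genotypes(lookup, all_ids)
        p = M.mean(axis=0) / 2.0
        keep = (p > 0.0) & (p < 1.0)
        n_train = ref_ids.size
        train_rows = np.flatnonzero(np.concatenate([obs_mask, np.zeros(val_ids.size, bool)]))
        val_rows = np.arange(n_train, n_train + val_ids.size)
        X = np.ones((y.size, 1))
        if model == "gblup":
            grm = vanraden_grm(M, blend_weight=opts["grm_blend"], center=opts["center"])
            K_inv = np.linalg.inv(grm.values)
            Z = np.zeros((y.size, all_ids.size))
            Z[np.arange(y.size), train_rows] = 1.0
            sol = solve_mme(y, X, Z, K_inv, lam, model_tag="GBLUP")
            gebv = sol.u[val_rows]
        else:
            Zc = (M[:, keep] - 2.0 * p[keep]) if opts["center"] else M[:, keep]
            denom = float(np.sum(2.0 * p[keep] * (1.0 - p[keep])))
            sig_alpha2 = variance_components.sigma_a2 / denom
            W = np.ones(keep.sum())
            alpha, b = snp_ridge(y, np.ones((y.size, 1)), Zc[train_rows], W,
                                 variance_components, sigma_alpha2=sig_alpha2)
            if not opts["force_identity_weights"]:
                genome = next(iter(study_bundle.values())).genome
                wv = window_weights(alpha, opts["window_halfwidth"],
                                    genome.marker_chrom[keep])
                alpha, b = snp_ridge(y, np.ones((y.size, 1)), Zc[train_rows], wv.weights,
                                     variance_components, sigma_alpha2=sig_alpha2)
            gebv = Zc[val_rows] @ alpha
            sol = MmeSolution(b=b, u=alpha, residual_rel=0.0, model_tag="wGBLUP")
        sol.validation_gebv = gebv
        sol.validation_ids = val_ids
        return sol

    if model in ("pblup", "ssgblup"):
        # pedigree-side animals: ancestor closure of reference + validation
        ref_pops = {id(lookup[int(i)][0]) for i in ref_ids}
        studies_used = []
        for study in study_bundle.values():
            rows_here = [lookup[int(i)][1] for i in np.concatenate([ref_ids, val_ids])
                         if lookup[int(i)][0] is study]
            if not rows_here:
                continue
            closure = _ancestor_closure(study, np.array(rows_here))
            studies_used.append((study, closure))
        id_list, sire_list, dam_list = [], [], []
        phen_list = []
        for study, closure in studies_used:
            ped = study.pedigree.iloc[closure]
            kept = set(ped["id"].astype(int))
            id_list.append(ped["id"].to_numpy())
            sire_list.append(np.where(ped["sire"].isin(kept), ped["sire"], 0))
            dam_list.append(np.where(ped["dam"].isin(kept), ped["dam"], 0))
            ph = study.phenotypes[closure].copy()
            if id(study) in ref_pops:
                # reference-population ancestors keep their records;
                # genotyped animals only contribute if in the reference
                gmask = study.genotyped[closure]
                ph[gmask] = np.nan
            else:
                ph[:] = np.nan
            phen_list.append(ph)
        ids_all = np.concatenate(id_list)
        sire_all = np.concatenate(sire_list).astype(np.int64)
        dam_all = np.concatenate(dam_list).astype(np.int64)
        phen_all = np.concatenate(phen_list)
        pos = {int(i): k for k, i in enumerate(ids_all)}
        # overlay the scenario's training records
        for i, yy in zip(train_ids, y):
            phen_all[pos[int(i)]] = yy
        sire_idx = np.array([pos.get(int(s), -1) if s else -1 for s in sire_all])
        dam_idx = np.array([pos.get(int(d), -1) if d else -1 for d in dam_all])
        n_all = ids_all.size
        a_inv = a_inverse_from_arrays(sire_idx, dam_idx)
        K_inv = a_inv
        tag = "PBLUP"
        if model == "ssgblup":
            gen_ids = np.concatenate([ref_ids, val_ids])
            gen_rows = np.array([pos[int(i)] for i in gen_ids])
            M = _gather_genotypes(lookup, gen_ids)
            G_star = opts.get("G_star")
            if G_star is None:
                G_star = vanraden_grm(M, blend_weight=opts["grm_blend"],
                                      center=opts["center"]).values
            A22 = _a22_block(studies_used, pos, gen_ids, lookup)
            corr = np.linalg.inv(G_star) - np.linalg.inv(A22)
            rows = np.repeat(gen_rows, gen_rows.size)
            cols = np.tile(gen_rows, gen_rows.size)
            K_inv = a_inv + sparse.coo_matrix(
                (corr.ravel(), (rows, cols)), shape=(n_all, n_all)
            ).tocsr()
            tag = "ssGBLUP"
        obs = np.flatnonzero(~np.isnan(phen_all))
        yv = phen_all[obs]
        X = np.ones((obs.size, 1))
        Z = sparse.csr_matrix(
            (np.ones(obs.size), (np.arange(obs.size), obs)), shape=(obs.size, n_all)
        )
        sol = solve_mme(yv, X, Z, K_inv, lam, model_tag=tag)
        val_rows = np.array([pos[int(i)] for i in val_ids])
        sol.validation_gebv = sol.u[val_rows]
        sol.validation_ids = val_ids
        return sol

    raise ValueError(f"unknown model {model!r}")


def _a22_block(studies_used, pos, gen_ids, lookup) -> np.ndarray:
    """Pedigree relationship block over genotyped animals (block-diagonal by population)."""
    n = gen_ids.size
    A22 = np.zeros((n, n))
    for study, closure in studies_used:
        mine = [k for k, i in enumerate(gen_ids) if lookup[int(i)][0] is study]
        if not mine:
            continue
        ped = study.pedigree.iloc[closure]
        ids = ped["id"].to_numpy()
        local = {int(i): r for r, i in enumerate(ids)}
        sire = np.array([local.get(int(s), -1) for s in ped["sire"]])
        dam = np.array([local.get(int(d), -1) for d in ped["dam"]])
        A = tabular_a(sire, dam)
        rows = np.array([local[int(gen_ids[k])] for k in mine])
        A22[np.ix_(mine, mine)] = A[np.ix_(rows, rows)]
    return A22
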