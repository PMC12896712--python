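"""Mixed-model machinery: pedigree and genomic relationship matrices,
single-step H-inverse, MME solutions, SNP ridge, window weights, REML."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from crosspop_gs import gsmodels


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


class TestNumeratorRelationship:
    def test_two_founders_identity(self):
        A = gsmodels.numerator_relationship(_ped([(1, 0, 0), (2, 0, 0)])).values
        np.testing.assert_allclose(A, np.eye(2))

    def test_parent_offspring_half(self):
        A = gsmodels.numerator_relationship(
            _ped([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        ).values
        assert A[2, 2] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(0.5)
        assert A[1, 2] == pytest.approx(0.5)

    def test_full_sibs_and_inbred_offspring(self):
        # full sibs 3,4 related 0.5; their offspring 5 inbred F=0.25
        A = gsmodels.numerator_relationship(
            _ped([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])
        ).values
        assert A[2, 3] == pytest.approx(0.5)
        assert A[4, 4] == pytest.approx(1.25)

    def test_unordered_pedigree_rejected(self):
        with pytest.raises(ValueError, match="topologically"):
            gsmodels.numerator_relationship(_ped([(1, 2, 0), (2, 0, 0)]))


class TestAInverse:
    def test_matches_dense_inverse_with_inbreeding(self, rng):
        # random 40-animal pedigree with overlapping matings
        sire = [-1] * 10
        dam = [-1] * 10
        for i in range(10, 40):
            s, d = rng.integers(0, i, 2)
            sire.append(int(s))
            dam.append(int(d) if d != s else -1)
        sire, dam = np.array(sire), np.array(dam)
        A = gsmodels.tabular_a(sire, dam)
        Ainv = gsmodels.a_inverse_from_arrays(sire, dam).toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(40), atol=1e-8)


class TestVanRadenGrm:
    def test_all_heterozygous_collapses_to_blend(self):
        M = np.ones((4, 6))
        g = gsmodels.vanraden_grm(M, frequencies=np.full(6, 0.5), blend_weight=0.1)
        np.testing.assert_allclose(g.values, 0.1 * np.eye(4), atol=1e-12)

    def test_two_by_two_hand_example(self):
        # Z = M - 2p = [[-1, 1], [1, -1]], sum 2 p (1-p) = 1.0
        M = np.array([[0.0, 2.0], [2.0, 0.0]])
        g = gsmodels.vanraden_grm(M, frequencies=np.array([0.5, 0.5]), blend_weight=0.0)
        np.testing.assert_allclose(g.values, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_hwe_population_mean_diagonal_near_one(self, rng):
        p = rng.uniform(0.1, 0.9, 2000)
        M = rng.binomial(2, p, (200, 2000)).astype(float)
        g = gsmodels.vanraden_grm(M, blend_weight=0.0)
        assert abs(np.diag(g.values).mean() - 1.0) < 0.05

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gsmodels.vanraden_grm(np.full((5, 3), 2.0))

    def test_blended_matrix_positive_definite(self, rng):
        M = rng.binomial(2, 0.5, (50, 30)).astype(float)
        g = gsmodels.vanraden_grm(M, blend_weight=0.05)
        assert np.linalg.eigvalsh(g.values).min() > 0


class TestHInverse:
    def _toy(self, rng):
        sire = np.array([-1, -1, 0, 0])
        dam = np.array([-1, -1, 1, 1])
        return gsmodels.tabular_a(sire, dam)

    def test_empty_genotyped_set_is_a_inverse(self, rng):
        A = self._toy(rng)
        H = gsmodels.h_inverse(A, np.zeros((0, 0)), np.array([], dtype=int))
        np.testing.assert_allclose(H.values, np.linalg.inv(A), atol=1e-10)

    def test_g_equal_a22_cancels(self, rng):
        A = self._toy(rng)
        gi = np.array([2, 3])
        H = gsmodels.h_inverse(A, A[np.ix_(gi, gi)], gi)
        np.testing.assert_allclose(H.values, np.linalg.inv(A), atol=1e-10)

    def test_matches_dense_assembly_oracle(self, rng):
        A = self._toy(rng)
        gi = np.array([1, 3])
        B = rng.normal(size=(2, 2))
        G = B @ B.T + 0.5 * np.eye(2)
        H = gsmodels.h_inverse(A, G, gi)
        oracle = np.linalg.inv(A).copy()
        oracle[np.ix_(gi, gi)] += np.linalg.inv(G) - np.linalg.inv(A[np.ix_(gi, gi)])
        np.testing.assert_allclose(H.values, oracle, atol=1e-8)

    def test_inverse_consistency_with_dense_h(self, rng):
        # H assembled from its textbook block formula, then inverted
        A = self._toy(rng)
        gi = np.array([2, 3])
        ni = np.array([0, 1])
        B = rng.normal(size=(2, 2))
        G = B @ B.T + 0.5 * np.eye(2)
        A11, A12 = A[np.ix_(ni, ni)], A[np.ix_(ni, gi)]
        A22 = A[np.ix_(gi, gi)]
        A22i = np.linalg.inv(A22)
        H = np.zeros((4, 4))
        H[np.ix_(gi, gi)] = G
        H[np.ix_(ni, gi)] = A12 @ A22i @ G
        H[np.ix_(gi, ni)] = (A12 @ A22i @ G).T
        H[np.ix_(ni, ni)] = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
        Hinv = gsmodels.h_inverse(A, G, gi).values
        np.testing.assert_allclose(Hinv @ H, np.eye(4), atol=1e-6)


class TestSolveMme:
    def test_intercept_ridge_closed_form(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        Z = np.eye(3)
        sol = gsmodels.solve_mme(y, X, Z, np.eye(3), lam=1.0)
        C = np.zeros((4, 4))
        C[0, 0] = 3.0
        C[0, 1:] = 1.0
        C[1:, 0] = 1.0
        C[1:, 1:] = 2.0 * np.eye(3)
        expected = np.linalg.solve(C, np.array([6.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(np.concatenate([sol.b, sol.u]), expected, atol=1e-8)

    def test_huge_lambda_shrinks_u_to_zero(self, rng):
        y = rng.normal(size=20)
        sol = gsmodels.solve_mme(y, np.ones((20, 1)), np.eye(20), np.eye(20), lam=1e12)
        assert np.abs(sol.u).max() < 1e-6

    def test_normal_equation_residual_small(self, rng):
        n = 30
        y = rng.normal(size=n)
        Z = np.eye(n)
        K = gsmodels.vanraden_grm(rng.binomial(2, 0.5, (n, 100)).astype(float)).values
        sol = gsmodels.solve_mme(y, np.ones((n, 1)), Z, np.linalg.inv(K), lam=1.4)
        assert sol.residual_rel < 1e-8

    def test_sparse_and_dense_paths_agree(self, rng):
        n = 25
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        Kinv = np.linalg.inv(gsmodels.vanraden_grm(
            rng.binomial(2, 0.5, (n, 80)).astype(float)).values)
        dense = gsmodels.solve_mme(y, X, np.eye(n), Kinv, 1.0)
        sp = gsmodels.solve_mme(y, X, sparse.eye(n, format="csr"),
                                sparse.csr_matrix(Kinv), 1.0)
        np.testing.assert_allclose(dense.u, sp.u, atol=1e-8)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            gsmodels.solve_mme(np.ones(3), np.ones((3, 1)), np.eye(3), np.eye(3), 0.0)


class TestEmReml:
    def test_matches_direct_likelihood_optimum(self, rng):
        # gene-drop half-sib families so h2 is identifiable at small n
        from scipy.optimize import minimize
        m, fam, off = 600, 15, 10
        p = rng.uniform(0.1, 0.9, m)
        rows = []
        for _ in range(fam):
            sh = (rng.random((2, m)) < p).astype(float)
            for _ in range(off):
                dh = (rng.random((2, m)) < p).astype(float)
                rows.append(np.where(rng.random(m) < 0.5, sh[0], sh[1])
                            + np.where(rng.random(m) < 0.5, dh[0], dh[1]))
        M = np.array(rows)
        n = len(M)
        K = gsmodels.vanraden_grm(M, blend_weight=0.05).values
        g = np.linalg.cholesky(K) @ rng.normal(0, np.sqrt(0.42), n)
        y = 1.0 + g + rng.normal(0, np.sqrt(0.58), n)
        X = np.ones((n, 1))

        def negll(theta):
            sa2, se2 = np.exp(theta)
            V = sa2 * K + se2 * np.eye(n)
            Vi = np.linalg.inv(V)
            B = X.T @ Vi @ X
            b = np.linalg.solve(B, X.T @ Vi @ y)
            r = y - X @ b
            return 0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(B)[1] + r @ Vi @ r)

        from scipy.optimize import minimize
        opt = minimize(negll, np.log([0.5, 0.5]), method="Nelder-Mead",
                       options=dict(xatol=1e-8, fatol=1e-10))
        sa2_star, se2_star = np.exp(opt.x)
        vc = gsmodels.em_reml(y, X, K, max_iter=2000)
        assert vc.sigma_a2 == pytest.approx(sa2_star, abs=2e-3)
        assert vc.sigma_e2 == pytest.approx(se2_star, abs=2e-3)


class TestSnpRidge:
    def test_zero_signal_gives_zero_effects(self, rng):
        Z = rng.normal(size=(30, 50))
        y = np.zeros(30)
        alpha, _ = gsmodels.snp_ridge(y, None, Z, np.ones(50),
                                      gsmodels.VarianceComponents(0.42, 0.58))
        np.testing.assert_allclose(alpha, 0.0, atol=1e-12)

    def test_single_snp_closed_form(self, rng):
        z = rng.normal(size=(40, 1))
        y = rng.normal(size=40)
        vc = gsmodels.VarianceComponents(0.3, 0.6)
        alpha, _ = gsmodels.snp_ridge(y, None, z, np.ones(1), vc)
        lam = vc.sigma_e2 / vc.sigma_a2
        expected = float(z[:, 0] @ y / (z[:, 0] @ z[:, 0] + lam))
        assert alpha[0] == pytest.approx(expected, abs=1e-10)

    def test_equivalence_with_gblup(self, rng):
        # 200 animals x 500 SNPs: identical validation GEBV via both routes
        p = rng.uniform(0.15, 0.85, 500)
        M = rng.binomial(2, p, (200, 500)).astype(float)
        phat = M.mean(axis=0) / 2
        keep = (phat > 0) & (phat < 1)
        Z = M[:, keep] - 2 * phat[keep]
        denom = float(np.sum(2 * phat[keep] * (1 - phat[keep])))
        y = rng.normal(size=150)
        vc = gsmodels.VarianceComponents(0.42, 0.58)
        # GBLUP route: G over all 200, first 150 phenotyped.  Centered G
        # is singular along the all-ones direction, so invert with a
        # vanishing blend; both routes are flat in that direction.
        G = gsmodels.vanraden_grm(M, blend_weight=1e-8).values
        Zinc = np.zeros((150, 200))
        Zinc[np.arange(150), np.arange(150)] = 1
        sol = gsmodels.solve_mme(y, np.ones((150, 1)), Zinc, np.linalg.inv(G),
                                 vc.variance_ratio)
        gebv_g = sol.u[150:]
        # SNP-ridge route on the training rows only
        alpha, _ = gsmodels.snp_ridge(y, np.ones((150, 1)), Z[:150], np.ones(keep.sum()),
                                      vc, sigma_alpha2=vc.sigma_a2 / denom)
        gebv_s = Z[150:] @ alpha
        r = np.corrcoef(gebv_g, gebv_s)[0, 1]
        assert r > 0.9999

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            gsmodels.snp_ridge(rng.normal(size=10), None, rng.normal(size=(10, 4)),
                               np.zeros(4), gsmodels.VarianceComponents(0.4, 0.6))


class TestWindowWeights:
    def test_s0_proportional_to_squared_effects(self):
        w = gsmodels.window_weights(np.array([1.0, 2.0, 3.0]), S=0)
        np.testing.assert_allclose(w.weights, np.array([1, 4, 9]) / (14 / 3))
        assert w.weights.mean() == pytest.approx(1.0, abs=1e-10)

    def test_constant_effects_uniform(self):
        w = gsmodels.window_weights(np.ones(5), S=2)
        np.testing.assert_allclose(w.weights, 1.0)

    def test_truncated_window_hand_example(self):
        # alpha = (0, 1, 0, 0, 2), S = 1, one chromosome:
        # raw = (1/2, 1/3, 1/3, 4/3, 2); C = 1 / mean(raw)
        alpha = np.array([0.0, 1.0, 0.0, 0.0, 2.0])
        raw = np.array([0.5, 1 / 3, 1 / 3, 4 / 3, 2.0])
        w = gsmodels.window_weights(alpha, S=1)
        np.testing.assert_allclose(w.weights, raw / raw.mean(), atol=1e-12)

    def test_all_zero_effects_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            w = gsmodels.window_weights(np.zeros(6), S=1)
        np.testing.assert_allclose(w.weights, 1.0)

    def test_windows_respect_chromosome_boundaries(self):
        alpha = np.array([2.0, 0.0, 0.0, 2.0])
        chrom = np.array([1, 1, 2, 2])
        w = gsmodels.window_weights(alpha, S=3, marker_chrom=chrom)
        # each chromosome averages only its own effects
        assert w.weights[0] == pytest.approx(w.weights[1])
        assert w.weights[2] == pytest.approx(w.weights[3])


class TestPredict:
    @pytest.fixture(scope="class")
    def scenario(self, tiny_trio):
        from crosspop_gs import refset
        return refset.single_population_scenario(tiny_trio["A"])

    def test_wgblup_identity_weights_equals_gblup(self, tiny_trio, scenario):
        vc = gsmodels.VarianceComponents(0.42, 0.58)
        opts = {"grm_blend": 1e-8, "force_identity_weights": True}
        g = gsmodels.predict("gblup", scenario, tiny_trio, vc, opts)
        w = gsmodels.predict("wgblup", scenario, tiny_trio, vc, opts)
        r = np.corrcoef(g.validation_gebv, w.validation_gebv)[0, 1]
        assert r > 0.9999
        np.testing.assert_allclose(g.validation_gebv, w.validation_gebv, atol=1e-6)

    def test_ssgblup_with_a22_equals_pblup(self, tiny_trio, scenario):
        vc = gsmodels.VarianceComponents(0.42, 0.58)
        study = tiny_trio["A"]
        A = gsmodels.numerator_relationship(study.pedigree[["id", "sire", "dam"]]).values
        gen_ids = np.concatenate([scenario.reference_ids, scenario.validation_ids])
        rows = study.rows_of(gen_ids)
        A22 = A[np.ix_(rows, rows)]
        p = gsmodels.predict("pblup", scenario, tiny_trio, vc)
        s = gsmodels.predict("ssgblup", scenario, tiny_trio, vc, {"G_star": A22})
        assert np.abs(p.validation_gebv - s.validation_gebv).max() < 1e-8

    def test_shrinkage_monotonic_in_lambda(self, tiny_trio, scenario):
        variances = []
        for lam_scale in (0.5, 2.0, 8.0):
            vc = gsmodels.VarianceComponents(0.42, 0.42 * lam_scale)
            sol = gsmodels.predict("gblup", scenario, tiny_trio, vc)
            variances.append(np.var(sol.validation_gebv))
        assert variances[0] >= variances[1] >= variances[2]

    def test_unknown_scenario_id_raises(self, tiny_trio, scenario):
        import dataclasses
        bad = dataclasses.replace(
            scenario, reference_ids=np.array([99_999_999]),
        )
        with pytest.raises(KeyError):
            gsmodels.predict("gblup", bad, tiny_trio,
                             gsmodels.VarianceComponents(0.42, 0.58))
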