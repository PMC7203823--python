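import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_genotypes
from vegwas.genotype_qc import GRM, compute_grm, compute_pcs
from vegwas.gwas_smr import (
    VarianceComponents,
    _gls_scan,
    _reml_profile,
    estimate_variance_components,
    mlma_loco,
    smr_significant,
    weighted_smr,
)


def random_grm(n, m, seed):
    rng = np.random.default_rng(seed)
    return compute_grm(make_genotypes(rng.binomial(2, 0.4, size=(n, m)).astype(float)))


def structured_grm(n=500, m=100, div=0.3, seed=0):
    """GRM with population structure (three groups with divergent allele
    frequencies) so the eigenvalue spread identifies the variance ratio."""
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(0.1, 0.9, m)
    f2 = np.clip(f1 + rng.normal(0, div, m), 0.05, 0.95)
    f3 = np.clip(f1 - rng.normal(0, div, m), 0.05, 0.95)
    k = n // 3
    dos = np.vstack(
        [
            rng.binomial(2, f1, size=(k, m)),
            rng.binomial(2, f2, size=(k, m)),
            rng.binomial(2, f3, size=(n - 2 * k, m)),
        ]
    ).astype(float)
    return compute_grm(make_genotypes(dos))


class TestReml:
    def test_null_simulation_sigma_g_near_zero(self):
        grm = structured_grm()
        n = grm.n
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            y = rng.normal(size=n)
            vc = estimate_variance_components(y, grm)
            if vc.sigma2_g < 0.05 * vc.total:
                hits += 1
        assert hits >= 45  # >= 90% of replicates

    def test_identity_grm_unidentifiable(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        vc = estimate_variance_components(y, GRM(matrix=np.eye(30)))
        assert not vc.identifiable
        assert vc.total == pytest.approx(np.var(y, ddof=1))

    def test_optimum_beats_random_grid(self):
        grm = random_grm(80, 200, 3)
        rng = np.random.default_rng(4)
        g = rng.multivariate_normal(np.zeros(80), grm.matrix + 1e-6 * np.eye(80))
        y = g + rng.normal(size=80)
        vc = estimate_variance_components(y, grm)
        lam, U = np.linalg.eigh(grm.matrix)
        ystar = U.T @ y
        xstar = U.T @ np.ones((80, 1))
        at_opt = -_reml_profile(vc.h2, lam, ystar, xstar)
        for h in rng.uniform(0, 0.99, size=20):
            assert at_opt >= -_reml_profile(h, lam, ystar, xstar) - 1e-6

    def test_recovers_heritable_signal(self):
        grm = random_grm(150, 400, 5)
        rng = np.random.default_rng(6)
        lam, U = np.linalg.eigh(grm.matrix)
        lam = np.clip(lam, 0, None)  # PSD draw of g ~ N(0, 3 G)
        g = U @ (np.sqrt(3.0 * lam) * rng.standard_normal(150))
        y = g + rng.normal(0, 1.0, size=150)
        vc = estimate_variance_components(y, grm)
        assert vc.sigma2_g > vc.sigma2_e  # true ratio 3:1

    def test_matches_brute_force_grid_reml(self):
        # independent oracle: full-matrix REML log-likelihood on a 2-D grid
        grm = random_grm(60, 150, 12)
        rng = np.random.default_rng(13)
        lam, U = np.linalg.eigh(grm.matrix)
        g = U @ (np.sqrt(np.clip(lam, 0, None) * 2.0) * rng.standard_normal(60))
        y = g + rng.normal(0, 1.0, size=60)
        vc = estimate_variance_components(y, grm)
        n = 60
        X = np.ones((n, 1))
        best = (-np.inf, None, None)
        for sg in np.linspace(0.01, 6, 35):
            for se in np.linspace(0.01, 4, 35):
                V = sg * grm.matrix + se * np.eye(n)
                Vinv = np.linalg.inv(V)
                XtVX = X.T @ Vinv @ X
                P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
                ll = -0.5 * (
                    np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1] + y @ P @ y
                )
                if ll > best[0]:
                    best = (ll, sg, se)
        assert vc.sigma2_g == pytest.approx(best[1], abs=0.3)
        assert vc.sigma2_e == pytest.approx(best[2], abs=0.3)


class TestGlsScan:
    def test_identity_covariance_reproduces_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n, m = 40, 6
        X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        lam, U = np.linalg.eigh(np.eye(n))
        res = _gls_scan(y, X, lam, U, VarianceComponents(0.0, 1.7))
        for j in range(m):
            fit = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            assert res["beta"][j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["se"][j] == pytest.approx(fit.bse[1], abs=1e-10)

    def test_brute_force_gls_oracle_30_individuals(self):
        rng = np.random.default_rng(8)
        n = 30
        gs = make_genotypes(rng.binomial(2, 0.4, size=(n, 20)).astype(float))
        grm = compute_grm(gs)
        y = rng.normal(size=n)
        vc = VarianceComponents(0.8, 1.3)
        lam, U = np.linalg.eigh(grm.matrix)
        res = _gls_scan(y, gs.dosages, lam, U, vc)
        V = vc.sigma2_g * grm.matrix + vc.sigma2_e * np.eye(n)
        Vinv = np.linalg.inv(V)
        for j in range(20):
            X = np.column_stack([np.ones(n), gs.dosages[:, j]])
            beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            assert res["beta"][j] == pytest.approx(beta[1], abs=1e-8)

    def test_monomorphic_flagged(self):
        rng = np.random.default_rng(9)
        n = 25
        X = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        X[:, 1] = 2.0
        lam, U = np.linalg.eigh(np.eye(n))
        res = _gls_scan(rng.normal(size=n), X, lam, U, VarianceComponents(0.0, 1.0))
        assert res["monomorphic"][1]
        assert res["beta"][1] == 0.0 and res["p"][1] == 1.0


class TestMlmaLoco:
    def test_planted_vqtl_top_hit(self, vqtl_dataset):
        gs, pheno, truth, _ = vqtl_dataset
        res = mlma_loco(pheno, gs)
        assert res.nsmallest(1, "p")["snp"].iloc[0] == truth.causal_vqtl_ids[0]
        assert res.nsmallest(1, "p")["p"].iloc[0] < 1e-4

    def test_p_value_wald_consistency(self, vqtl_dataset):
        from scipy import stats

        gs, pheno, _, _ = vqtl_dataset
        res = mlma_loco(pheno, gs)
        ok = ~res["monomorphic"]
        chi2 = (res["beta"][ok] / res["se"][ok]) ** 2
        np.testing.assert_allclose(res["p"][ok], stats.chi2.sf(chi2, 1), atol=1e-12)


class TestWeightedSmr:
    def _setup(self, seed=10, n=60, m=8):
        rng = np.random.default_rng(seed)
        gs = make_genotypes(rng.binomial(2, 0.4, size=(n, m)).astype(float))
        pheno = pd.DataFrame(
            {
                "doe_id": gs.samples["doe_id"],
                "ve": rng.gamma(2.0, 2.0, size=n),
                "weight": rng.uniform(4, 6, size=n),
                "population": "base",
            }
        )
        pcs = compute_pcs(compute_grm(gs), k=5)
        return gs, pheno, pcs

    def test_constant_weights_match_unweighted_ranking(self):
        gs, pheno, pcs = self._setup()
        pheno["weight"] = 4.5
        res_w = weighted_smr(pheno, gs, pcs)
        res_u = weighted_smr(pheno, gs, pcs, weights=np.ones(len(pheno)))
        np.testing.assert_allclose(res_w["p"], res_u["p"], atol=1e-10)

    def test_doubling_weights_invariant(self):
        gs, pheno, pcs = self._setup()
        res1 = weighted_smr(pheno, gs, pcs)
        res2 = weighted_smr(pheno, gs, pcs, weights=2 * pheno["weight"].to_numpy())
        for col in ("beta", "se", "p"):
            np.testing.assert_allclose(res1[col], res2[col], atol=1e-10)

    def test_hand_computed_wls_normal_equations(self):
        # 6 observations, intercept + dosage only (no PCs): solve the
        # weighted normal equations (X' W X) b = X' W y by hand
        gs = make_genotypes(np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]]))
        y = np.array([1.0, 2.0, 4.0, 0.5, 2.5, 3.5])
        w = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 2.0])
        pheno = pd.DataFrame(
            {"doe_id": gs.samples["doe_id"], "ve": y, "weight": w, "population": "base"}
        )
        res = weighted_smr(pheno, gs, np.zeros((6, 0)))
        X = np.column_stack([np.ones(6), gs.dosages[:, 0]])
        W = np.diag(w)
        expected = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert res["beta"][0] == pytest.approx(expected[1], abs=1e-10)

    def test_nonpositive_weights_rejected(self):
        gs, pheno, pcs = self._setup()
        with pytest.raises(ValueError):
            weighted_smr(pheno, gs, pcs, weights=np.zeros(len(pheno)))


class TestSignificance:
    def _frame(self, ps):
        return pd.DataFrame(
            {
                "snp": [f"s{i}" for i in range(len(ps))],
                "chrom": "1",
                "bp": range(len(ps)),
                "p": ps,
            }
        )

    def test_tiers(self):
        out = smr_significant(self._frame([9e-5, 1.8e-4, 5e-4]))
        tiers = dict(zip(out["snp"], out["tier"]))
        assert tiers == {"s0": "strict", "s1": "near"}

    def test_boundary_is_strict(self):
        out = smr_significant(self._frame([1e-4, 2e-4]))
        assert dict(zip(out["snp"], out["tier"])) == {"s0": "near"}
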