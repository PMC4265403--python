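"""Whole-genome regression: closed-form oracles, shrinkage, DIC."""

import numpy as np
import pandas as pd
import pytest

from sprucegs.genotypes import GenotypeMatrix
from sprucegs.markers import MarkerRegression, compute_dic, compute_gebv
from sprucegs.pedigree import Pedigree


def _toy_panel(n=20, m=10, seed=0, p=0.4):
    rng = np.random.default_rng(seed)
    data = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    # guarantee polymorphism
    data[0] = 0
    data[1] = 2
    return GenotypeMatrix(data, [f"I{i}" for i in range(n)],
                          [f"M{k:02d}" for k in range(m)])


def _toy_y(G, h2=0.6, seed=1):
    rng = np.random.default_rng(seed)
    b = rng.normal(size=G.n_markers)
    g = G.data.astype(float) @ b
    g = (g - g.mean()) / g.std()
    y = g * np.sqrt(h2) + rng.normal(0, np.sqrt(1 - h2), G.n_individuals)
    return pd.Series(y, index=G.ids)


class TestRidgeOracle:
    def test_fixed_variances_match_closed_form(self):
        """With both variances frozen the RR posterior mean is the ridge
        solution (Zc'Zc + lambda I)^-1 Zc'(y - ybar) on centered dosages."""
        G = _toy_panel()
        y = _toy_y(G)
        sigma_u, sigma_e = 0.05, 0.5
        res = MarkerRegression(y, G, "rr").fit(
            iterations=60000, burnin=5000, thin=10, seed=2,
            fix_variances=(sigma_u, sigma_e))
        Zc = G.data.astype(float)
        Zc -= Zc.mean(axis=0)
        lam = sigma_e / sigma_u
        yc = y.to_numpy() - y.mean()
        expected = np.linalg.solve(Zc.T @ Zc + lam * np.eye(G.n_markers),
                                   Zc.T @ yc)
        np.testing.assert_allclose(res.effects.to_numpy(), expected, atol=0.02)

    def test_null_signal_gives_null_effects(self):
        G = _toy_panel(n=50, m=20, seed=3)
        y = pd.Series(np.zeros(50), index=G.ids)
        res = MarkerRegression(y, G, "rr").fit(iterations=2000, burnin=500,
                                               thin=2, seed=4)
        assert np.abs(res.effects).max() < 0.05


class TestGEBV:
    def test_hand_product(self):
        G = GenotypeMatrix(np.array([[0, 1, 2], [2, 0, 1], [1, 1, 1],
                                     [0, 0, 2], [2, 2, 0]], dtype=np.int8),
                           list("abcde"), ["m1", "m2", "m3"])
        effects = pd.Series([0.5, -1.0, 2.0], index=["m1", "m2", "m3"])
        gebv = compute_gebv(effects, G)
        np.testing.assert_allclose(gebv.to_numpy(),
                                   [3.0, 3.0, 1.5, 4.0, -1.0])

    def test_single_marker_equals_dosage(self):
        G = _toy_panel(m=1)
        gebv = compute_gebv(pd.Series([1.0], index=G.markers), G)
        np.testing.assert_allclose(gebv.to_numpy(), G.data[:, 0])

    def test_zero_effects(self):
        G = _toy_panel()
        gebv = compute_gebv(pd.Series(0.0, index=G.markers), G)
        assert (gebv == 0).all()

    def test_marker_mismatch_raises(self):
        G = _toy_panel()
        with pytest.raises(ValueError, match="marker sets"):
            compute_gebv(pd.Series([1.0], index=["OTHER"]), G)

    def test_gebv_recomputable_from_effects(self, clean_geno, adjusted_pheno):
        y = adjusted_pheno.set_index("id")["T1"]
        res = MarkerRegression(y, clean_geno, "rr").fit(
            iterations=800, burnin=200, thin=2, seed=5)
        again = compute_gebv(res.effects, clean_geno)
        np.testing.assert_allclose(res.gebv.to_numpy(), again.to_numpy(),
                                   atol=1e-10)


class TestDIC:
    def test_constant_deviance(self):
        dic, pd_eff = compute_dic(np.full(100, 42.0), 42.0)
        assert dic == 42.0 and pd_eff == 0.0

    def test_conjugate_normal_mean_oracle(self):
        """Known-variance normal mean: pD -> 1 and DIC matches the
        analytic value within Monte-Carlo error."""
        rng = np.random.default_rng(6)
        sigma2 = 2.0
        y = rng.normal(1.0, np.sqrt(sigma2), 400)
        n = len(y)
        theta = rng.normal(y.mean(), np.sqrt(sigma2 / n), 40000)
        devs = np.array([((y - t) ** 2).sum() / sigma2 for t in theta]) \
            + n * np.log(2 * np.pi * sigma2)
        d_hat = ((y - y.mean()) ** 2).sum() / sigma2 \
            + n * np.log(2 * np.pi * sigma2)
        dic, pd_eff = compute_dic(devs, d_hat)
        assert pd_eff == pytest.approx(1.0, abs=0.05)
        assert dic == pytest.approx(d_hat + 2.0, abs=0.1)

    def test_polygenic_term_improves_fit_majority(self, complete_pop,
                                                  adjusted_pheno, clean_geno):
        """On pedigree-structured data, adding the polygenic term to RR
        lowers DIC in the majority of replicate chains."""
        y = adjusted_pheno.set_index("id")["T1"]
        wins = 0
        for seed in (7, 8, 9):
            rr = MarkerRegression(y, clean_geno, "rr").fit(
                iterations=1500, burnin=400, thin=3, seed=seed)
            rra = MarkerRegression(y, clean_geno, "rra",
                                   pedigree=complete_pop.pedigree).fit(
                iterations=1500, burnin=400, thin=3, seed=seed)
            wins += rra.dic <= rr.dic
        assert wins >= 2


class TestLasso:
    def test_forced_large_lambda_shrinks_harder(self):
        """Pinning the regularization parameter high makes LASSO shrink
        more than RR on the same data."""
        G = _toy_panel(n=60, m=30, seed=10)
        y = _toy_y(G, h2=0.4, seed=11)
        rr = MarkerRegression(y, G, "rr").fit(iterations=3000, burnin=800,
                                              thin=3, seed=12)
        lasso = MarkerRegression(y, G, "lasso",
                                 lambda_shape=1e7, lambda_rate=1e3).fit(
            iterations=3000, burnin=800, thin=3, seed=12)
        assert np.median(np.abs(lasso.effects)) < np.median(np.abs(rr.effects))
        assert float(lasso.lambda_chain.mean()) > 50

    def test_null_signal(self):
        G = _toy_panel(n=50, m=20, seed=13)
        y = pd.Series(np.zeros(50), index=G.ids)
        res = MarkerRegression(y, G, "lasso").fit(iterations=2000, burnin=500,
                                                  thin=2, seed=14)
        assert np.abs(res.effects).max() < 0.05

    def test_tracks_ridge_estimates(self, clean_geno, adjusted_pheno):
        """RR and LASSO marker effects correlate strongly on polygenic
        data (the two priors disagree only about tail shrinkage)."""
        y = adjusted_pheno.set_index("id")["T1"]
        rr = MarkerRegression(y, clean_geno, "rr").fit(
            iterations=2000, burnin=500, thin=3, seed=15)
        la = MarkerRegression(y, clean_geno, "lasso").fit(
            iterations=2000, burnin=500, thin=3, seed=15)
        assert np.corrcoef(rr.effects, la.effects)[0, 1] >= 0.9


class TestInvariants:
    def test_column_permutation_equivariance(self):
        """Permuting marker columns permutes the estimated effects
        identically (canonical marker-ID processing order)."""
        G = _toy_panel(n=40, m=15, seed=16)
        y = _toy_y(G, seed=17)
        res1 = MarkerRegression(y, G, "rr").fit(iterations=500, burnin=100,
                                                thin=2, seed=18)
        perm = np.random.default_rng(19).permutation(G.n_markers)
        G2 = G.take_markers(perm)
        res2 = MarkerRegression(y, G2, "rr").fit(iterations=500, burnin=100,
                                                 thin=2, seed=18)
        pd.testing.assert_series_equal(res1.effects.sort_index(),
                                       res2.effects.sort_index())

    def test_gebv_variance_bounded_by_phenotypic(self, clean_geno,
                                                 adjusted_pheno):
        y = adjusted_pheno.set_index("id")["T1"]
        for seed in (20, 21):
            res = MarkerRegression(y, clean_geno, "rr").fit(
                iterations=1200, burnin=300, thin=3, seed=seed)
            train = res.gebv.reindex(y.dropna().index)
            assert train.var() <= y.dropna().var()

    def test_rra_identity_relationship_degenerates_gracefully(self):
        G = _toy_panel(n=30, m=10, seed=22)
        y = _toy_y(G, seed=23)
        ped = Pedigree.from_records([(i, None, None) for i in G.ids])
        res = MarkerRegression(y, G, "rra", pedigree=ped).fit(
            iterations=800, burnin=200, thin=2, seed=24)
        assert np.isfinite(res.effects).all()
        assert np.isfinite(res.polygenic).all()
        assert np.isfinite(res.dic)

    def test_unknown_variant_rejected(self):
        G = _toy_panel()
        with pytest.raises(ValueError, match="variant"):
            MarkerRegression(_toy_y(G), G, "bayesC")
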