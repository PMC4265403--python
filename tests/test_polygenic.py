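"""Phenotype preparation and animal-model fits against small oracles."""

import numpy as np
import pandas as pd
import pytest

from sprucegs.pedigree import Pedigree
from sprucegs.polygenic import (AnimalModel, adjust_phenotypes, hpd_interval,
                                posterior_mode, summarize_posterior)


def brute_force_hpd(samples, prob=0.95):
    """Exhaustive shortest-interval search over all sample pairs."""
    s = np.sort(samples)
    n = len(s)
    need = int(np.ceil(prob * n))
    best = (s[0], s[-1])
    for i in range(n - need + 1):
        j = i + need - 1
        if s[j] - s[i] < best[1] - best[0]:
            best = (s[i], s[j])
    return best


class TestAdjustPhenotypes:
    def test_three_block_hand_computation(self):
        """Two-step oracle: subtract block means, divide by site SD."""
        pheno = pd.DataFrame({
            "id": [f"i{k}" for k in range(6)],
            "site": ["S1"] * 6,
            "block": ["b1", "b1", "b2", "b2", "b3", "b3"],
            "T": [1.0, 3.0, 10.0, 14.0, 100.0, 90.0],
        })
        adj, rep = adjust_phenotypes(pheno, ["T"])
        resid = np.array([-1, 1, -2, 2, 5, -5], dtype=float)
        expected = resid / resid.std(ddof=1)
        np.testing.assert_allclose(adj["T"], expected)
        assert rep["T"]["n_outliers"] == 0

    def test_planted_outlier_censored(self):
        rng = np.random.default_rng(0)
        n = 200
        pheno = pd.DataFrame({
            "id": [f"i{k}" for k in range(n)],
            "site": ["S1"] * n,
            "block": ["b1"] * (n // 2) + ["b2"] * (n // 2),
            "T": rng.normal(size=n),
        })
        pheno.loc[5, "T"] += 10.0
        adj, rep = adjust_phenotypes(pheno, ["T"])
        assert rep["T"]["n_outliers"] == 1
        assert np.isnan(adj.loc[5, "T"])
        assert adj["T"].isna().sum() == 1

    def test_constant_within_blocks_gives_zero(self):
        pheno = pd.DataFrame({
            "id": list("abcd"), "site": ["S1"] * 4,
            "block": ["b1", "b1", "b2", "b2"], "T": [3.0, 3.0, 7.0, 7.0],
        })
        adj, rep = adjust_phenotypes(pheno, ["T"])
        assert (adj["T"].fillna(0.0) == 0.0).all()
        assert rep["T"]["n_outliers"] == 0

    def test_tiny_block_warns_and_uses_site_mean(self):
        pheno = pd.DataFrame({
            "id": list("abcde"), "site": ["S1"] * 5,
            "block": ["b1", "b1", "b1", "b1", "lonely"],
            "T": [1.0, 2.0, 3.0, 4.0, 10.0],
        })
        with pytest.warns(UserWarning, match="< 2 observations"):
            adjust_phenotypes(pheno, ["T"])


class TestPosteriorSummaries:
    def test_constant_chain(self):
        out = summarize_posterior(np.ones(200))
        assert out == {"mode": 1.0, "hpd_lower": 1.0, "hpd_upper": 1.0}

    def test_normal_hpd_matches_quantiles(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(100_000)
        lo, hi = hpd_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)
        assert posterior_mode(draws) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_hpd_matches_brute_force(self, seed):
        """Shortest interval equals the exhaustive search, including on a
        bimodal chain where the interval must bridge or pick one mode."""
        rng = np.random.default_rng(seed)
        chain = np.concatenate([rng.normal(-3, 0.3, 300),
                                rng.normal(2, 1.0, 200)])
        assert hpd_interval(chain) == pytest.approx(brute_force_hpd(chain))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.arange(10))


def _one_way_design(n_groups=80, reps=5, sigma_a=1.0, sigma_e=1.0, seed=5):
    rng = np.random.default_rng(seed)
    ids = [f"G{i}" for i in range(n_groups)]
    ped = Pedigree.from_records([(i, None, None) for i in ids])
    a = rng.normal(0, np.sqrt(sigma_a), n_groups)
    rows = []
    for i, iid in enumerate(ids):
        for r in range(reps):
            rows.append((iid, "S1", "b1", a[i] + rng.normal(0, np.sqrt(sigma_e))))
    pheno = pd.DataFrame(rows, columns=["id", "site", "block", "T"])
    return ped, pheno


class TestUnivariateModel:
    def test_matches_balanced_reml_oracle(self):
        """With A = I and a balanced repeated-records design the model is
        one-way random effects; posteriors track the closed-form REML
        (ANOVA) estimates within 10%."""
        ped, pheno = _one_way_design()
        reps = 5
        groups = pheno.groupby("id")["T"]
        grand = pheno["T"].mean()
        msb = reps * ((groups.mean() - grand) ** 2).sum() / (len(groups) - 1)
        mse = ((pheno["T"] - pheno["id"].map(groups.mean())) ** 2).sum() / (
            len(pheno) - len(groups))
        reml_sa = (msb - mse) / reps
        reml_se = mse

        res = AnimalModel(pheno, ped, "T").fit(iterations=8000, burnin=2000,
                                               thin=5, seed=1)
        post_sa = res.chains["sigma2_a"].mean()
        post_se = res.chains["sigma2_e"].mean()
        assert post_sa == pytest.approx(reml_sa, rel=0.10)
        assert post_se == pytest.approx(reml_se, rel=0.10)

    def test_ebv_invariant_to_phenotype_shift(self, complete_pop, adjusted_pheno):
        """Adding a constant to every phenotype is absorbed by the fixed
        effects and leaves the EBVs untouched (same seed)."""
        kw = dict(iterations=1200, burnin=200, thin=5, seed=3,
                  check_convergence=False)
        r1 = AnimalModel(adjusted_pheno, complete_pop.pedigree, "T1").fit(**kw)
        shifted = adjusted_pheno.copy()
        shifted["T1"] = shifted["T1"] + 5.0
        r2 = AnimalModel(shifted, complete_pop.pedigree, "T1").fit(**kw)
        np.testing.assert_allclose(r1.ebv, r2.ebv, atol=1e-8)

    def test_h2_chain_bounded(self, complete_pop, adjusted_pheno):
        res = AnimalModel(adjusted_pheno, complete_pop.pedigree, "T1").fit(
            iterations=1500, burnin=300, thin=5, seed=4,
            check_convergence=False)
        h2 = res.chains["h2"]
        assert ((h2 >= 0) & (h2 <= 1)).all()

    def test_dic_favors_true_relatedness(self, complete_pop, adjusted_pheno):
        """Fitting the generative pedigree beats a no-genetics null
        (intercept + residual only) on DIC for heritable data."""
        kw = dict(iterations=3000, burnin=800, thin=5, seed=5,
                  check_convergence=False)
        true_fit = AnimalModel(adjusted_pheno, complete_pop.pedigree,
                               "T1").fit(**kw)
        # oracle null: conjugate Gibbs for y = mu + e
        y = adjusted_pheno["T1"].dropna().to_numpy()
        rng = np.random.default_rng(5)
        n = len(y)
        devs = []
        sig = y.var()
        for it in range(600):
            mu = rng.normal(y.mean(), np.sqrt(sig / n))
            sse = ((y - mu) ** 2).sum()
            sig = sse / rng.chisquare(n - 1)
            if it >= 100:
                devs.append(n * np.log(2 * np.pi * sig) + sse / sig)
        sse_hat = ((y - y.mean()) ** 2).sum()
        d_hat = n * np.log(2 * np.pi * sse_hat / n) + n
        null_dic = 2 * np.mean(devs) - d_hat
        assert true_fit.dic < null_dic


class TestBivariateModel:
    def test_requires_disjoint_sites(self, complete_pop, adjusted_pheno):
        doubled = pd.concat([adjusted_pheno, adjusted_pheno.assign(
            site=adjusted_pheno["site"].map({"S1": "S2", "S2": "S1"}))])
        with pytest.raises(ValueError, match="disjoint"):
            AnimalModel(doubled, complete_pop.pedigree, "T1",
                        bivariate_by="site")

    def test_chains_respect_bounds(self, complete_pop, adjusted_pheno):
        res = AnimalModel(adjusted_pheno, complete_pop.pedigree, "T1",
                          bivariate_by="site").fit(
            iterations=2000, burnin=400, thin=4, seed=6,
            check_convergence=False)
        assert res.r12_chain.abs().max() <= 1.0
        for col in ("h2_site1", "h2_site2"):
            assert res.chains[col].between(0, 1).all()
        summ = res.summary()
        assert (summ["hpd_lower"] <= summ["hpd_upper"]).all()

    def test_marginal_matches_univariate(self, complete_pop, adjusted_pheno):
        """Site-1 genetic variance from the bivariate fit agrees with a
        univariate fit on the site-1 records within MCMC error."""
        kw = dict(iterations=4000, burnin=1000, thin=5,
                  check_convergence=False)
        biv = AnimalModel(adjusted_pheno, complete_pop.pedigree, "T1",
                          bivariate_by="site").fit(seed=7, **kw)
        s1 = adjusted_pheno[adjusted_pheno["site"] == "S1"]
        uni = AnimalModel(s1, complete_pop.pedigree, "T1").fit(seed=8, **kw)
        h2_biv = biv.chains["h2_site1"].mean()
        h2_uni = uni.chains["h2"].mean()
        assert h2_biv == pytest.approx(h2_uni, abs=0.12)
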