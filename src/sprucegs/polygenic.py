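"""Bayesian individual-tree ("animal") models for multi-site trials.

Phenotype preparation (block adjustment, outlier removal, within-site
standardization) plus Gibbs-sampled univariate and bivariate animal
models.  The univariate model is

    y = Xb + Za + e,   a ~ N(0, A sigma2_a),  e ~ N(0, I sigma2_e),

with fixed block effects b and the pedigree numerator matrix A.  The
bivariate model treats the same trait on two disjoint sites as two
correlated traits: var(a1, a2) = C (x) A with a 2x2 genetic covariance
matrix C, and a structurally zero residual covariance because no tree is
measured on both sites.  Variance priors are inverse-Wishart (scaled
inverse-chi-square in the univariate case) with scale equal to the
phenotypic variance divided by the number of random terms and degree of
belief 1 (univariate) or 2 (bivariate).  Posteriors are summarized by
the kernel-density mode and the 95% highest-posterior-density interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde

from sprucegs._samplers import animal_bivariate, animal_univariate
from sprucegs.pedigree import Pedigree
from sprucegs.relatedness import RelationshipMatrix, invert_A

__all__ = ["adjust_phenotypes", "AnimalModel", "AnimalModelResults",
           "posterior_mode", "hpd_interval", "summarize_posterior",
           "fit_univariate", "fit_bivariate"]


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def posterior_mode(chain: np.ndarray) -> float:
    """Marginal posterior mode via Gaussian KDE (Silverman bandwidth)."""
    chain = np.asarray(chain, dtype=float)
    if chain.std() == 0:
        return float(chain[0])
    kde = gaussian_kde(chain, bw_method="silverman")
    grid = np.linspace(chain.min(), chain.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(chain: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    s = np.sort(np.asarray(chain, dtype=float))
    n = len(s)
    k = int(np.ceil(prob * n))  # number of samples the interval must hold
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def summarize_posterior(chain: np.ndarray, prob: float = 0.95) -> dict:
    """Mode and HPD bounds of a posterior sample (chain length >= 100)."""
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 1 or len(chain) < 100:
        raise ValueError("need a 1-D chain of at least 100 samples")
    lo, hi = hpd_interval(chain, prob)
    return {"mode": posterior_mode(chain), "hpd_lower": lo, "hpd_upper": hi}


def _split_rhat(chain: np.ndarray) -> float:
    """Potential scale reduction on a single chain split in half."""
    n = len(chain) // 2
    halves = np.stack([chain[:n], chain[n: 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((w * (n - 1) / n + b / n) / w))


# ---------------------------------------------------------------------------
# phenotype preparation
# ---------------------------------------------------------------------------

def adjust_phenotypes(pheno: pd.DataFrame, traits: list[str] | None = None,
                      sd_limit: float = 3.0) -> tuple[pd.DataFrame, dict]:
    """Block-adjust, censor outliers and standardize within site.

    Per trait: subtract least-squares block means (blocks nested in
    sites), set residuals beyond ``sd_limit`` residual standard
    deviations to missing, then divide by the within-site standard
    deviation of the adjusted values.  Blocks with fewer than 2
    observations fall back to the site mean (with a warning).

    Returns the table with adjusted trait columns and a report with the
    outlier count per trait.
    """
    if traits is None:
        meta = {"id", "site", "block"}
        traits = [c for c in pheno.columns if c not in meta]
    out = pheno.copy()
    report = {}
    for trait in traits:
        y = out[trait].astype(float)
        site_mean = y.groupby(out["site"]).transform("mean")
        grp = y.groupby([out["site"], out["block"]])
        counts = grp.transform("count")
        block_mean = grp.transform("mean")
        if (counts < 2).any():
            warnings.warn(f"{trait}: blocks with < 2 observations use the site mean")
            block_mean = block_mean.where(counts >= 2, site_mean)
        resid = y - block_mean
        sd = resid.std()
        outliers = resid.abs() > sd_limit * sd
        resid[outliers] = np.nan
        within_site_sd = resid.groupby(out["site"]).transform("std")
        out[trait] = resid / within_site_sd
        report[trait] = {"n_outliers": int(outliers.sum())}
    return out, report


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class AnimalModelResults:
    """Posterior summaries of one animal-model fit.

    Variance-component chains are thinned post-burn-in samples;
    ``ebv`` holds posterior-mean breeding values for every pedigree
    individual (for the bivariate model, the value at the observed site
    where available, otherwise the across-site mean).
    """

    model: "AnimalModel"
    chains: pd.DataFrame
    ebv: pd.Series
    ebv_by_site: pd.DataFrame | None
    dic: float
    pd_effective: float
    converged: bool

    @property
    def h2_chain(self) -> pd.DataFrame:
        cols = [c for c in self.chains.columns if c.startswith("h2")]
        return self.chains[cols]

    @property
    def r12_chain(self) -> pd.Series | None:
        return self.chains["r12"] if "r12" in self.chains else None

    def summary(self) -> pd.DataFrame:
        """Mode and 95% HPD per parameter, one row each."""
        rows = {}
        for col in self.chains.columns:
            if col == "deviance":
                continue
            rows[col] = summarize_posterior(self.chains[col].to_numpy())
        df = pd.DataFrame(rows).T
        df.attrs["dic"] = self.dic
        return df

    def plot_trace(self, params=None, path=None):
        """Trace plots of the variance-component chains."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        params = params or [c for c in self.chains.columns if c != "deviance"]
        fig, axes = plt.subplots(len(params), 1, figsize=(7, 2 * len(params)),
                                 squeeze=False)
        for ax, p in zip(axes[:, 0], params):
            ax.plot(self.chains[p].to_numpy(), lw=0.5)
            ax.set_ylabel(p)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


class AnimalModel:
    """Univariate or two-site bivariate animal model.

    Parameters
    ----------
    pheno : DataFrame with columns ``id, site, block`` and the trait.
        Pass adjusted/standardized phenotypes (see
        :func:`adjust_phenotypes`); missing trait values are excluded
        from the likelihood.
    pedigree : Pedigree covering all phenotyped individuals.
    trait : trait column to model.
    bivariate_by : ``None`` for the univariate model or the name of the
        site column (typically ``"site"``) to treat the trait on two
        disjoint sites as correlated traits.
    relationship : ``"A"`` (pedigree, default) or a
        :class:`RelationshipMatrix` whose inverse should drive the
        genetic covariance (e.g. a genomic K).
    """

    def __init__(self, pheno: pd.DataFrame, pedigree: Pedigree, trait: str,
                 bivariate_by: str | None = None,
                 relationship: str | RelationshipMatrix = "A"):
        self.pheno = pheno
        self.pedigree = pedigree
        self.trait = trait
        self.bivariate_by = bivariate_by
        obs = pheno.dropna(subset=[trait])
        missing_ids = set(obs["id"].astype(str)) - set(pedigree.ids)
        if missing_ids:
            raise ValueError(
                f"phenotyped individuals absent from pedigree: {sorted(missing_ids)[:5]}")
        if bivariate_by is not None:
            sites = sorted(obs[bivariate_by].unique())
            if len(sites) != 2:
                raise ValueError("the bivariate model needs exactly two sites")
            per_ind = obs.groupby("id")[bivariate_by].nunique()
            if (per_ind > 1).any():
                raise ValueError(
                    "bivariate two-site model requires disjoint site membership; "
                    "some individuals have records on both sites")
            self.sites = sites
        self._obs = obs
        if isinstance(relationship, RelationshipMatrix):
            aligned = relationship.subset(pedigree.ids)
            self._ainv = sp.csr_matrix(np.linalg.inv(
                aligned.values + 1e-8 * np.eye(len(pedigree.ids))))
        else:
            if relationship != "A":
                raise ValueError("relationship must be 'A' or a RelationshipMatrix")
            self._ainv = invert_A(pedigree).tocsr()

    # -- shared encodings ------------------------------------------------

    def _encode(self):
        obs = self._obs
        ids = self.pedigree.ids
        pos = {iid: i for i, iid in enumerate(ids)}
        rec_ind = np.asarray([pos[i] for i in obs["id"].astype(str)], dtype=np.int64)
        block_labels = (obs["site"].astype(str) + "|" + obs["block"].astype(str))
        blocks = sorted(block_labels.unique())
        bpos = {b: j for j, b in enumerate(blocks)}
        rec_block = np.asarray([bpos[b] for b in block_labels], dtype=np.int64)
        y = obs[self.trait].to_numpy(dtype=float)
        return y, rec_ind, rec_block, len(blocks), pos

    def fit(self, iterations: int = 26000, burnin: int = 6000, thin: int = 20,
            seed: int = 0, fixed_prior_var: float = 1e8,
            check_convergence: bool = True) -> AnimalModelResults:
        """Run the Gibbs sampler and summarize the chains.

        Defaults are desk-scale (26,000 iterations, 6,000 burn-in, thin
        20, i.e. 1,000 saved samples); production chains scale all three
        by 10.
        """
        if iterations <= burnin:
            raise ValueError("iterations must exceed burnin")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        if self.bivariate_by is None:
            return self._fit_univariate(iterations, burnin, thin, seed,
                                        fixed_prior_var, check_convergence)
        return self._fit_bivariate(iterations, burnin, thin, seed,
                                   fixed_prior_var, check_convergence)

    def _fit_univariate(self, iterations, burnin, thin, seed, fixed_prior_var,
                        check_convergence=True):
        y, rec_ind, rec_block, n_blocks, pos = self._encode()
        n_ind = len(self.pedigree.ids)
        # group record indices by individual (CSR-style)
        ind_rec_idx = np.argsort(rec_ind, kind="stable").astype(np.int64)
        counts = np.bincount(rec_ind, minlength=n_ind)
        ind_rec_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

        vp = float(np.var(y, ddof=1))
        nu, V = 1.0, vp / 2.0
        sa, se, dev, a_mean, b_mean, a_chain = animal_univariate(
            y, rec_block, n_blocks, ind_rec_ptr, ind_rec_idx,
            self._ainv.indptr.astype(np.int64),
            self._ainv.indices.astype(np.int64),
            self._ainv.data.astype(np.float64),
            int(iterations), int(burnin), int(thin),
            nu, V, nu, V, float(fixed_prior_var), int(seed) & 0x7FFFFFFF,
        )
        chains = pd.DataFrame({
            "sigma2_a": sa, "sigma2_e": se, "h2": sa / (sa + se),
            "deviance": dev,
        })
        # DIC at posterior means
        e_hat = y.copy()
        for r in range(len(y)):
            e_hat[r] -= b_mean[rec_block[r]] + a_mean[rec_ind[r]]
        se_bar = se.mean()
        d_hat = len(y) * np.log(2 * np.pi * se_bar) + (e_hat @ e_hat) / se_bar
        d_bar = dev.mean()
        dic = 2 * d_bar - d_hat
        converged = max(_split_rhat(sa), _split_rhat(se)) < 1.1
        if not converged and check_convergence:
            warnings.warn("variance-component chains show split-Rhat > 1.1; "
                          "increase iterations")
        ebv = pd.Series(a_mean, index=pd.Index(self.pedigree.ids, name="id"),
                        name="ebv")
        return AnimalModelResults(self, chains, ebv, None, float(dic),
                                  float(d_bar - d_hat), converged)

    def _fit_bivariate(self, iterations, burnin, thin, seed, fixed_prior_var,
                       check_convergence=True):
        y, rec_ind, rec_block, n_blocks, pos = self._encode()
        obs = self._obs
        site_code = {s: k for k, s in enumerate(self.sites)}
        rec_site = np.asarray([site_code[s] for s in obs[self.bivariate_by]],
                              dtype=np.int64)
        n_ind = len(self.pedigree.ids)
        ind_rec = np.full(n_ind, -1, dtype=np.int64)
        ind_site = np.zeros(n_ind, dtype=np.int64)
        for r, i in enumerate(rec_ind):
            ind_rec[i] = r
            ind_site[i] = rec_site[r]

        vp = float(np.var(y, ddof=1))
        nu_c, Vc = 2.0, vp / 2.0
        nu_e, Ve = 2.0, vp / 2.0
        chain, a_mean, a_obs_chain = animal_bivariate(
            y, rec_block, rec_site, n_blocks, ind_rec, ind_site,
            self._ainv.indptr.astype(np.int64),
            self._ainv.indices.astype(np.int64),
            self._ainv.data.astype(np.float64),
            int(iterations), int(burnin), int(thin),
            nu_c, Vc, nu_e, Ve, float(fixed_prior_var), int(seed) & 0x7FFFFFFF,
        )
        c11, c22, c12, se1, se2, dev = chain.T
        with np.errstate(invalid="ignore"):
            r12 = c12 / np.sqrt(c11 * c22)
        chains = pd.DataFrame({
            "C11": c11, "C22": c22, "C12": c12,
            "sigma2_e1": se1, "sigma2_e2": se2,
            "h2_site1": c11 / (c11 + se1), "h2_site2": c22 / (c22 + se2),
            "r12": r12, "deviance": dev,
        })
        # DIC at posterior means; block effects are profiled out as the
        # per-block means of the genetic-value-corrected residuals
        bmask = obs["site"].astype(str) + "|" + obs["block"].astype(str)
        a_hat = np.array([a_mean[i, ind_site[i]] for i in range(n_ind)])
        resid0 = y - a_hat[rec_ind]
        bm = pd.Series(resid0).groupby(bmask.to_numpy()).transform("mean").to_numpy()
        e_hat = resid0 - bm
        se_bar = np.where(rec_site == 0, se1.mean(), se2.mean())
        d_hat = float(np.sum(np.log(2 * np.pi * se_bar) + e_hat**2 / se_bar))
        d_bar = float(dev.mean())
        dic = 2 * d_bar - d_hat
        converged = max(_split_rhat(c11), _split_rhat(c22),
                        _split_rhat(se1), _split_rhat(se2)) < 1.1
        if not converged and check_convergence:
            warnings.warn("variance-component chains show split-Rhat > 1.1; "
                          "increase iterations")
        ids = pd.Index(self.pedigree.ids, name="id")
        ebv_by_site = pd.DataFrame(a_mean, index=ids,
                                   columns=[str(s) for s in self.sites])
        observed = ind_rec >= 0
        ebv_vals = np.where(observed, a_hat, a_mean.mean(axis=1))
        ebv = pd.Series(ebv_vals, index=ids, name="ebv")
        return AnimalModelResults(self, chains, ebv, ebv_by_site, float(dic),
                                  float(d_bar - d_hat), converged)


def fit_univariate(pheno: pd.DataFrame, pedigree: Pedigree, trait: str,
                   relationship="A", **fit_kw) -> AnimalModelResults:
    """Convenience wrapper: univariate animal model fit."""
    return AnimalModel(pheno, pedigree, trait,
                       relationship=relationship).fit(**fit_kw)


def fit_bivariate(pheno: pd.DataFrame, pedigree: Pedigree, trait: str,
                  site_col: str = "site", relationship="A",
                  **fit_kw) -> AnimalModelResults:
    """Convenience wrapper: two-site bivariate animal model fit."""
    return AnimalModel(pheno, pedigree, trait, bivariate_by=site_col,
                       relationship=relationship).fit(**fit_kw)
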