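"""Whole-genome marker regression: ridge (RR-BLUP) and Bayesian LASSO.

The model is  y = mu + Z u + a + e  on adjusted, standardized phenotypes,
with Z the 0/1/2 dosage matrix, u random marker effects, and an optional
pedigree polygenic term a ~ N(0, A sigma2_a).  Ridge regression assigns
all markers one common Gaussian variance (uniform shrinkage, the
many-small-effects assumption); the Bayesian LASSO assigns a double
exponential prior, i.e. marker-specific Gaussian variances tau2_k with
exponential mixing controlled by a regularization parameter lambda that
is itself sampled (Gamma hyperprior on lambda^2, defaults shape 0.52 and
rate 1e-4).  The sum of marker effects over an individual's genotype is
its genomic estimated breeding value (GEBV).

Variance components carry scaled inverse-chi-square priors with df = 3
and scale set so the prior mode splits the phenotypic variance equally
among the active random terms.

Markers are processed in marker-ID order inside the sampler, so permuting
the columns of the input panel permutes the estimated effects identically
under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sprucegs._samplers import marker_gibbs
from sprucegs.genotypes import GenotypeMatrix
from sprucegs.pedigree import Pedigree
from sprucegs.polygenic import hpd_interval, posterior_mode
from sprucegs.relatedness import invert_A

__all__ = ["MarkerRegression", "MarkerRegressionResults", "compute_gebv",
           "compute_dic", "VARIANTS"]

VARIANTS = {"a": "A", "rr": "RR", "rra": "RRA", "l": "L", "lasso": "L",
            "la": "LA", "lassoa": "LA"}

_PRIOR_DF = 3.0


def compute_gebv(effects: pd.Series, G: GenotypeMatrix) -> pd.Series:
    """GEBV_i = sum_k Z_ik u_k on raw dosages (no intercept, no polygenic).

    The effect index must match the genotype panel exactly (any order).
    """
    if set(effects.index) != set(G.markers):
        raise ValueError("marker sets of effects and genotypes differ")
    u = effects.reindex(G.markers).to_numpy(dtype=float)
    if G.missing_mask.any():
        raise ValueError("GEBV requires complete genotypes")
    vals = G.data.astype(float) @ u
    return pd.Series(vals, index=pd.Index(G.ids, name="id"), name="gebv")


def compute_dic(deviance_chain: np.ndarray, deviance_at_mean: float
                ) -> tuple[float, float]:
    """(DIC, pD): DIC = mean deviance + pD, pD = mean deviance - D(theta_bar)."""
    d_bar = float(np.mean(deviance_chain))
    p_d = d_bar - float(deviance_at_mean)
    return d_bar + p_d, p_d


@dataclass
class MarkerRegressionResults:
    """Posterior summaries of one whole-genome regression fit."""

    model: "MarkerRegression"
    effects: pd.Series            # posterior-mean marker effects
    intercept: float
    polygenic: pd.Series | None   # posterior-mean a per pedigree individual
    chains: pd.DataFrame          # sigma2_u, sigma2_a, sigma2_e, lambda2, deviance
    dic: float
    pd_effective: float

    @property
    def gebv(self) -> pd.Series:
        """GEBVs of the training individuals."""
        return compute_gebv(self.effects, self.model.genotypes)

    def predict(self, G: GenotypeMatrix, include_polygenic: bool = False
                ) -> pd.Series:
        """Marker-based predictions for (possibly new) individuals."""
        pred = compute_gebv(self.effects, G)
        if include_polygenic:
            if self.polygenic is None:
                raise ValueError("fit has no polygenic term")
            pred = pred.add(self.polygenic.reindex(pred.index).fillna(0.0))
        return pred

    @property
    def lambda_chain(self) -> pd.Series | None:
        if self.model.variant in ("L", "LA"):
            return np.sqrt(self.chains["lambda2"])
        return None

    def summary(self) -> pd.DataFrame:
        rows = {}
        active = {"A": ["sigma2_a", "sigma2_e"],
                  "RR": ["sigma2_u", "sigma2_e"],
                  "RRA": ["sigma2_u", "sigma2_a", "sigma2_e"],
                  "L": ["lambda2", "sigma2_e"],
                  "LA": ["lambda2", "sigma2_a", "sigma2_e"]}[self.model.variant]
        for col in active:
            c = self.chains[col].to_numpy()
            lo, hi = hpd_interval(c)
            rows[col] = {"mean": c.mean(), "mode": posterior_mode(c),
                         "hpd_lower": lo, "hpd_upper": hi}
        df = pd.DataFrame(rows).T
        df.attrs["dic"] = self.dic
        df.attrs["pD"] = self.pd_effective
        return df


class MarkerRegression:
    """Bayesian whole-genome regression on standardized phenotypes.

    Parameters
    ----------
    y : Series of adjusted+standardized phenotypes indexed by individual
        ID; missing values are dropped.
    genotypes : complete (imputed) dosage panel covering at least the
        phenotyped individuals.
    variant : 'a' (pedigree only), 'rr', 'rra', 'lasso' or 'lassoa'
        (case-insensitive; 'l'/'la' accepted).  Variants ending in 'a'
        add the pedigree polygenic term and require ``pedigree``.
    """

    def __init__(self, y: pd.Series, genotypes: GenotypeMatrix,
                 variant: str = "rr", pedigree: Pedigree | None = None,
                 lambda_shape: float = 0.52, lambda_rate: float = 1e-4):
        key = str(variant).lower()
        if key not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(set(VARIANTS))}")
        self.variant = VARIANTS[key]
        self.use_polygenic = self.variant in ("A", "RRA", "LA")
        self.use_markers = self.variant != "A"
        self.use_lasso = self.variant in ("L", "LA")
        if self.use_polygenic and pedigree is None:
            raise ValueError(f"variant {self.variant} requires a pedigree")
        y = y.dropna()
        y.index = y.index.astype(str)
        missing = set(y.index) - set(genotypes.ids)
        if self.use_markers and missing:
            raise ValueError(f"phenotyped individuals lack genotypes: {sorted(missing)[:5]}")
        self.y = y
        self.genotypes = genotypes
        self.pedigree = pedigree
        self.lambda_shape = float(lambda_shape)
        self.lambda_rate = float(lambda_rate)

    def fit(self, iterations: int = 6000, burnin: int = 1000, thin: int = 5,
            seed: int = 0, fix_variances: tuple[float, float] | None = None
            ) -> MarkerRegressionResults:
        """Run the Gibbs sampler.

        ``fix_variances=(sigma2_u, sigma2_e)`` freezes both variances
        (no sampling), which reduces ridge regression to its closed-form
        posterior - used for oracle checks and calibrated fits.
        """
        y_ids = list(self.y.index)
        yv = self.y.to_numpy(dtype=float)
        N = len(yv)
        if N < 3:
            raise ValueError("need at least 3 phenotyped individuals")

        # canonical marker order: sort columns by marker ID
        if self.use_markers:
            order = np.argsort(np.asarray(self.genotypes.markers))
            sorted_markers = [self.genotypes.markers[k] for k in order]
            sub = self.genotypes.select_individuals(y_ids)
            if sub.missing_mask.any():
                raise ValueError("genotypes must be complete (imputed) before fitting")
            Z = sub.data.astype(np.float64)[:, order]
            Z -= Z.mean(axis=0)
            Z = np.asfortranarray(Z)
            sum_var_z = float((Z ** 2).sum(axis=0).sum() / max(N - 1, 1))
        else:
            sorted_markers = []
            Z = np.asfortranarray(np.zeros((N, 0)))
            sum_var_z = 1.0

        # pedigree plumbing (identity fallback when no polygenic term)
        if self.use_polygenic:
            ped_ids = self.pedigree.ids
            pos = {iid: i for i, iid in enumerate(ped_ids)}
            rec_ind = np.asarray([pos[i] for i in y_ids], dtype=np.int64)
            ainv = invert_A(self.pedigree).tocsr()
        else:
            ped_ids = y_ids
            rec_ind = np.arange(N, dtype=np.int64)
            ainv = sp.identity(N, format="csr")
        n_ind = len(ped_ids)
        ind_rec_idx = np.argsort(rec_ind, kind="stable").astype(np.int64)
        counts = np.bincount(rec_ind, minlength=n_ind)
        ind_rec_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

        # priors: df = 3, scale so the prior mode splits var(y) equally
        # (floored so a degenerate constant y still yields proper priors)
        vy = max(float(np.var(yv, ddof=1)), 1e-6)
        n_terms = 1 + int(self.use_markers) + int(self.use_polygenic)
        share = vy / n_terms
        to_scale = (_PRIOR_DF + 2.0) / _PRIOR_DF
        Se = share * to_scale
        Sa = share * to_scale if self.use_polygenic else 0.1
        Su = (share / sum_var_z) * to_scale if self.use_markers else 0.1

        if fix_variances is not None:
            init_su, init_se = float(fix_variances[0]), float(fix_variances[1])
            sample_su = sample_se = False
        else:
            init_su = Su * _PRIOR_DF / (_PRIOR_DF + 2.0) if self.use_markers else 0.1
            init_se = share
            sample_su, sample_se = True, True

        u_mean, mu_mean, a_mean, chain = marker_gibbs(
            yv, Z, ind_rec_ptr, ind_rec_idx,
            ainv.indptr.astype(np.int64), ainv.indices.astype(np.int64),
            ainv.data.astype(np.float64),
            self.use_polygenic, self.use_lasso,
            int(iterations), int(burnin), int(thin),
            _PRIOR_DF, Su, _PRIOR_DF, Sa, _PRIOR_DF, Se,
            self.lambda_shape, self.lambda_rate,
            sample_su, sample_se, init_su, init_se,
            int(seed) & 0x7FFFFFFF,
        )
        chains = pd.DataFrame(chain, columns=["sigma2_u", "sigma2_a",
                                              "sigma2_e", "lambda2", "deviance"])
        # deviance at posterior means
        e_hat = yv - mu_mean - Z @ u_mean
        if self.use_polygenic:
            e_hat = e_hat - a_mean[rec_ind]
        se_bar = float(chains["sigma2_e"].mean())
        d_hat = N * np.log(2 * np.pi * se_bar) + float(e_hat @ e_hat) / se_bar
        dic, p_d = compute_dic(chains["deviance"].to_numpy(), d_hat)

        effects = pd.Series(u_mean, index=pd.Index(sorted_markers, name="marker"),
                            name="effect")
        if self.use_markers:
            effects = effects.reindex(self.genotypes.markers)
        polygenic = (pd.Series(a_mean, index=pd.Index(ped_ids, name="id"),
                               name="polygenic")
                     if self.use_polygenic else None)
        return MarkerRegressionResults(self, effects, float(mu_mean), polygenic,
                                       chains, float(dic), float(p_d))


def fit_rr(y, genotypes, pedigree=None, with_polygenic=False, **fit_kw):
    """Ridge-regression fit ('rr' or, with the pedigree term, 'rra')."""
    variant = "rra" if with_polygenic else "rr"
    return MarkerRegression(y, genotypes, variant, pedigree).fit(**fit_kw)


def fit_lasso(y, genotypes, pedigree=None, with_polygenic=False, **fit_kw):
    """Bayesian-LASSO fit ('lasso' or, with the pedigree term, 'lassoa')."""
    variant = "lassoa" if with_polygenic else "lasso"
    return MarkerRegression(y, genotypes, variant, pedigree).fit(**fit_kw)
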