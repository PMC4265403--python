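"""Single-marker mixed-model association (EMMAX style) and subset rules.

Variance components of the null model  y = Xb + g + e, g ~ N(0, R sg2)
are estimated once by REML through the eigendecomposition of the
relationship matrix R (exact 1-D optimization over the variance ratio);
every marker is then tested by generalized least squares with the
covariance held fixed at the null estimates, giving a 1-df F test per
marker.  On top of the scan sit the five marker-subset selection rules
used for subset cross-validation: significant markers under A- or
K-controlled scans, the largest absolute effects from a full
ridge-with-pedigree fit, a random draw, and the highest minor allele
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from sprucegs.genotypes import GenotypeMatrix
from sprucegs.relatedness import RelationshipMatrix

__all__ = ["NullVarianceComponents", "ScanResult", "MarkerSubset",
           "fit_null_vc", "smr_scan", "select_subset", "SUBSET_RULES"]

SUBSET_RULES = ("SMR_A_P05", "SMR_K_P05", "TOP_ABS_RRA", "RANDOM", "HMAF")


@dataclass
class NullVarianceComponents:
    """REML variance components of the marker-free mixed model.

    Holds the eigen-rotation of R so the scan can reuse it: ``U`` are
    eigenvectors, ``d`` eigenvalues, ``delta`` the residual/genetic
    variance ratio at the REML optimum.
    """

    sigma2_g: float
    sigma2_e: float
    delta: float
    loglik: float
    relationship_kind: str
    U: np.ndarray = field(repr=False)
    d: np.ndarray = field(repr=False)
    y_rot: np.ndarray = field(repr=False)
    X_rot: np.ndarray = field(repr=False)

    @property
    def heritability_like(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _reml_neg_loglik(log_delta: float, d, yr, Xr) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    n, q = Xr.shape
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWy = Xr.T @ (w * yr)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(np.sum(w * resid ** 2))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - q) * np.log(rss) + np.sum(np.log(d + delta)) + logdet_xwx)
    return -ll


def fit_null_vc(y: np.ndarray | pd.Series, X: np.ndarray,
                R: RelationshipMatrix | np.ndarray,
                kind: str | None = None) -> NullVarianceComponents:
    """Exact 1-D REML fit of (sigma2_g, sigma2_e) under covariance R.

    ``y`` and rows of ``X``/``R`` must be aligned.  Numerically negative
    eigenvalues of R are floored at 1e-8 (with a warning).
    """
    if isinstance(R, RelationshipMatrix):
        kind = kind or R.kind
        R = R.values
    kind = kind or "R"
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    d, U = np.linalg.eigh(R)
    if d.min() < -1e-8:
        warnings.warn("relationship matrix is not PSD; flooring eigenvalues")
    d = np.clip(d, 1e-8, None)
    yr = U.T @ y
    Xr = U.T @ X

    grid = np.linspace(-10, 10, 41)
    vals = [_reml_neg_loglik(g, d, yr, Xr) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(g0 - 1.0, g0 + 1.0), args=(d, yr, Xr),
        method="bounded", options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (d + delta)
    n, q = Xr.shape
    XtWX = Xr.T @ (w[:, None] * Xr)
    beta = np.linalg.solve(XtWX, Xr.T @ (w * yr))
    resid = yr - Xr @ beta
    sigma2_g = float(np.sum(w * resid ** 2) / (n - q))
    return NullVarianceComponents(
        sigma2_g=sigma2_g, sigma2_e=sigma2_g * delta, delta=delta,
        loglik=-float(res.fun), relationship_kind=kind,
        U=U, d=d, y_rot=yr, X_rot=Xr,
    )


@dataclass
class ScanResult:
    """Per-marker GLS estimates and F tests plus the null components."""

    table: pd.DataFrame  # effect, se, F, p, flagged per marker
    null_vc: NullVarianceComponents

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def smr_scan(y, G: GenotypeMatrix, X: np.ndarray,
             null_vc: NullVarianceComponents) -> ScanResult:
    """EMMAX scan: GLS per marker with covariance fixed at the null fit.

    Markers collinear with the fixed effects (zero GLS variance) are
    flagged and reported with p = 1.
    """
    if G.missing_mask.any():
        raise ValueError("scan requires complete genotypes")
    yr, Xr, d, U = null_vc.y_rot, null_vc.X_rot, null_vc.d, null_vc.U
    n, q = Xr.shape
    if G.n_individuals != n:
        raise ValueError("genotypes and null model cover different individuals")
    w = 1.0 / (d + null_vc.delta)

    Zr = U.T @ G.data.astype(float)
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWX_inv = np.linalg.inv(XtWX)
    WX = w[:, None] * Xr
    # project y and the markers onto the orthocomplement of X under W
    Py = w * yr - WX @ (XtWX_inv @ (WX.T @ yr))
    A1 = WX.T @ Zr                               # q x m
    zPz = (w[:, None] * Zr * Zr).sum(axis=0) - np.einsum(
        "qm,qk,km->m", A1, XtWX_inv, A1)
    zPy = Zr.T @ Py
    yPy = float(yr @ Py)

    with np.errstate(divide="ignore", invalid="ignore"):
        flagged = zPz <= 1e-10
        safe = np.where(flagged, 1.0, zPz)
        u_hat = zPy / safe
        rss = yPy - u_hat ** 2 * safe
        df_e = n - q - 1
        sigma2 = rss / df_e
        F = np.where(flagged, 0.0, u_hat ** 2 * safe / sigma2)
        se = np.sqrt(sigma2 / safe)
        p = stats.f.sf(F, 1, df_e)
    p = np.where(flagged, 1.0, p)
    u_hat = np.where(flagged, 0.0, u_hat)
    se = np.where(flagged, np.nan, se)
    table = pd.DataFrame(
        {"effect": u_hat, "se": se, "F": np.clip(F, 0.0, None), "p": p,
         "flagged": flagged},
        index=pd.Index(G.markers, name="marker"),
    )
    return ScanResult(table=table, null_vc=null_vc)


@dataclass
class MarkerSubset:
    """Ordered, de-duplicated marker list from one selection rule."""

    rule: str
    markers: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.markers)


def select_subset(rule: str, scan: ScanResult | None = None,
                  effects: pd.Series | None = None,
                  genotypes: GenotypeMatrix | None = None,
                  size: int = 600, alpha: float = 0.05,
                  seed: int | None = None,
                  provenance: dict | None = None) -> MarkerSubset:
    """Apply one of the five subset rules.

    SMR rules keep all markers with p below ``alpha`` (no multiplicity
    correction - the rule is a screen, not an inference), ordered by
    absolute effect; TOP_ABS_RRA / RANDOM / HMAF return exactly ``size``
    markers.  Ties break by (criterion descending, marker ID ascending)
    so subsets are platform-independent.
    """
    rule = rule.upper()
    if rule not in SUBSET_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {SUBSET_RULES}")
    prov = dict(provenance or {})

    if rule.startswith("SMR"):
        if scan is None:
            raise ValueError(f"rule {rule} needs a ScanResult")
        sig = scan.table[scan.table["p"] < alpha].reset_index()
        sig["absu"] = sig["effect"].abs()
        sig = sig.sort_values(["absu", "marker"], ascending=[False, True])
        markers = list(sig["marker"])
        prov["alpha"] = alpha
    elif rule == "TOP_ABS_RRA":
        if effects is None:
            raise ValueError("rule TOP_ABS_RRA needs marker effects")
        if size > len(effects):
            raise ValueError("requested subset exceeds panel size")
        df = pd.DataFrame({"absu": effects.abs()})
        df["marker"] = df.index
        df = df.sort_values(["absu", "marker"], ascending=[False, True])
        markers = list(df.index[:size])
    elif rule == "RANDOM":
        if genotypes is None:
            raise ValueError("rule RANDOM needs the genotype panel")
        if size > genotypes.n_markers:
            raise ValueError("requested subset exceeds panel size")
        rng = np.random.default_rng(seed)
        pick = rng.choice(genotypes.n_markers, size=size, replace=False)
        markers = sorted(genotypes.markers[k] for k in pick)
        prov["seed"] = seed
    else:  # HMAF
        if genotypes is None:
            raise ValueError("rule HMAF needs the genotype panel")
        if size > genotypes.n_markers:
            raise ValueError("requested subset exceeds panel size")
        df = pd.DataFrame({"maf": genotypes.maf(),
                           "marker": genotypes.markers})
        df = df.sort_values(["maf", "marker"], ascending=[False, True])
        markers = list(df["marker"][:size])
    return MarkerSubset(rule=rule, markers=markers, provenance=prov)
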