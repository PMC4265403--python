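"""Pedigree (A) and realized genomic (K) relationship matrices.

A is the numerator relationship matrix from the tabular method; its
sparse inverse follows Henderson's rules with inbreeding.  K is the
marker-based realized relationship matrix: dosage codes are oriented to
the minor allele, centered by twice the allele frequency and the
cross-product is normalized so that the mean diagonal equals 1, putting
K on the same scale as A.  A spectral scan of K summarizes population
structure (variance captured per eigenvector), and class-wise summaries
compare realized coefficients against their pedigree expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sprucegs.genotypes import GenotypeMatrix
from sprucegs.pedigree import Pedigree

__all__ = ["RelationshipMatrix", "StructureScan", "build_A", "invert_A",
           "build_K", "structure_scan", "relatedness_summary"]


@dataclass
class RelationshipMatrix:
    """Dense symmetric kinship-scale matrix with individual IDs.

    ``kind`` is ``"A"`` (pedigree expectation) or ``"K"`` (realized);
    for K the normalizer ``k`` (mean diagonal of QQ') is stored.
    """

    kind: str
    ids: list[str]
    values: np.ndarray
    normalizer: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match number of IDs")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, kind: str = "K") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(kind, [str(i) for i in df.index], df.to_numpy())

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.asarray([pos[i] for i in ids])
        return RelationshipMatrix(self.kind, list(ids),
                                  self.values[np.ix_(idx, idx)], self.normalizer)


@dataclass
class StructureScan:
    """Eigenvalues of K (descending) and variance fraction per axis."""

    eigenvalues: np.ndarray
    fractions: np.ndarray

    @property
    def first_fraction(self) -> float:
        return float(self.fractions[0])


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders have diagonal 1 and are mutually unrelated; thereafter
    ``a_ii = 1 + a_sd/2`` and ``a_ij = (a_js + a_jd)/2`` with unknown
    parents contributing zero.
    """
    n = len(pedigree)
    order = pedigree.topological_order
    sire, dam = pedigree.parent_indices()
    rank = np.empty(n, dtype=np.intp)
    rank[order] = np.arange(n)
    # re-encode parents into topological rank space
    s = np.where(sire[order] >= 0, rank[np.clip(sire[order], 0, None)], -1)
    d = np.where(dam[order] >= 0, rank[np.clip(dam[order], 0, None)], -1)
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    # back to input order: entry (i, j) lives at (rank[i], rank[j])
    A = A[np.ix_(rank, rank)]
    return RelationshipMatrix("A", pedigree.ids, A)


def invert_A(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A via Henderson's rules with inbreeding.

    Inbreeding coefficients come from :func:`build_A`; the Mendelian
    sampling variance of individual i is ``0.5 - (F_s + F_d)/4`` with a
    missing parent's F replaced by -1 (so one unknown parent gives 0.75
    and two give 1).  Rows/columns follow the pedigree's input order.
    """
    A = build_A(pedigree)
    F = np.diag(A.values) - 1.0
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s_i, d_i = sire[i], dam[i]
        fs = F[s_i] if s_i >= 0 else -1.0
        fd = F[d_i] if d_i >= 0 else -1.0
        d_ms = 0.5 - 0.25 * (fs + fd)
        alpha = 1.0 / d_ms
        add(i, i, alpha)
        for p in (s_i, d_i):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s_i, d_i):
            for q in (s_i, d_i):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_K(G: GenotypeMatrix) -> RelationshipMatrix:
    """Realized genomic relationship matrix from complete genotypes.

    Codes are oriented so the counted allele is the minor one (ties keep
    the input orientation), centered by 2p per marker (Q = M - P), and
    K = QQ'/k with k the mean diagonal of QQ', so mean(diag K) = 1.
    """
    if G.missing_mask.any():
        raise ValueError("K requires complete genotypes; impute first")
    p = G.allele_freq()
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic markers have zero variance; filter first")
    M = G.data.astype(float)
    flip = p > 0.5
    M[:, flip] = 2.0 - M[:, flip]
    p = np.where(flip, 1.0 - p, p)
    Q = M - 2.0 * p
    QQ = Q @ Q.T
    k = np.trace(QQ) / G.n_individuals
    return RelationshipMatrix("K", list(G.ids), QQ / k, normalizer=float(k))


def structure_scan(K: RelationshipMatrix) -> StructureScan:
    """Spectral decomposition of K; fraction of variance per eigenvector.

    Numerically negative eigenvalues are floored at zero when forming the
    fractions; the raw eigenvalues are reported unchanged.
    """
    V = K.values
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    lam = np.linalg.eigvalsh(V)[::-1]
    clipped = np.clip(lam, 0.0, None)
    fractions = clipped / clipped.sum()
    return StructureScan(eigenvalues=lam, fractions=fractions)


def _pairwise_classes(pedigree: Pedigree) -> dict[str, np.ndarray]:
    """Boolean upper-triangle masks per relationship class (vectorized)."""
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    idx = np.arange(n)
    po = (sire[None, :] == idx[:, None]) | (dam[None, :] == idx[:, None])
    po = po | po.T
    share_s = (sire[:, None] == sire[None, :]) & (sire[:, None] >= 0)
    share_d = (dam[:, None] == dam[None, :]) & (dam[:, None] >= 0)
    cross_sd = (sire[:, None] == dam[None, :]) & (sire[:, None] >= 0)
    cross_ds = (dam[:, None] == sire[None, :]) & (dam[:, None] >= 0)
    n_shared = (share_s | cross_sd).astype(int) + (share_d | cross_ds).astype(int)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    po &= upper
    full = upper & ~po & (n_shared >= 2)
    half = upper & ~po & (n_shared == 1)
    unrel = upper & ~po & (n_shared == 0)
    return {"parent_offspring": po, "full_sib": full, "half_sib": half,
            "unrelated": unrel}


def relatedness_summary(K: RelationshipMatrix, pedigree: Pedigree) -> pd.DataFrame:
    """Quartile summary of K entries per pedigree relationship class.

    Rows: unrelated, half-sib, full-sib, parent-offspring (empty classes
    are omitted).  Columns: n_pairs, median, q1, q3, min, max.
    """
    if list(K.ids) != pedigree.ids:
        K = K.subset(pedigree.ids)
    masks = _pairwise_classes(pedigree)
    rows = {}
    for name, mask in masks.items():
        vals = K.values[mask]
        if vals.size == 0:
            continue
        rows[name] = {
            "n_pairs": vals.size,
            "median": np.median(vals),
            "q1": np.quantile(vals, 0.25),
            "q3": np.quantile(vals, 0.75),
            "min": vals.min(),
            "max": vals.max(),
        }
    return pd.DataFrame(rows).T
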