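"""Dosage genotype matrix (individuals x markers, codes 0/1/2, missing allowed).

The matrix is stored as ``int8`` with ``-1`` marking missing calls.  The
per-marker frequency of the second (counted) allele is cached and
recomputed whenever the matrix is subset or mutated.  Readers/writers
cover a plain TSV dialect (header = marker IDs, first column = individual
ID, cells 0/1/2/NA) and the PLINK ``--recode A`` RAW dialect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

MISSING = -1


class GenotypeMatrix:
    """Individuals-by-markers dosage codes with a missing mask."""

    def __init__(self, data: np.ndarray, ids, markers):
        data = np.asarray(data)
        if data.ndim != 2:
            raise ValueError("genotype data must be 2-D (individuals x markers)")
        ids = [str(i) for i in ids]
        markers = [str(m) for m in markers]
        if data.shape != (len(ids), len(markers)):
            raise ValueError("data shape does not match id/marker counts")
        valid = np.isin(data, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing (-1/NA)")
        self.data = data.astype(np.int8)
        self.ids = ids
        self.markers = markers
        self._freq: np.ndarray | None = None

    # -- shape / masks ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.copy(), self.ids, self.markers)

    # -- statistics ------------------------------------------------------

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (second) allele per marker, from
        non-missing calls; NaN for markers with no calls."""
        if self._freq is None:
            obs = self.data != MISSING
            counts = np.where(obs, self.data, 0).sum(axis=0)
            n_called = obs.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                self._freq = np.where(n_called > 0, counts / (2.0 * n_called), np.nan)
        return self._freq

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=1)

    # -- subsetting ------------------------------------------------------

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.data[:, keep], self.ids, [self.markers[k] for k in keep]
        )

    def take_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.data[keep], [self.ids[k] for k in keep], self.markers
        )

    def select_markers(self, marker_ids) -> "GenotypeMatrix":
        pos = {m: k for k, m in enumerate(self.markers)}
        missing = [m for m in marker_ids if m not in pos]
        if missing:
            raise KeyError(f"markers absent from panel: {missing[:5]}")
        return self.take_markers(np.asarray([pos[m] for m in marker_ids]))

    def select_individuals(self, individual_ids) -> "GenotypeMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in individual_ids if i not in pos]
        if missing:
            raise KeyError(f"individuals absent from matrix: {missing[:5]}")
        return self.take_individuals(np.asarray([pos[i] for i in individual_ids]))

    # -- IO --------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            np.where(self.data == MISSING, np.nan, self.data),
            index=pd.Index(self.ids, name="id"),
            columns=self.markers,
        )
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        data = df.to_numpy(dtype=float)
        data = np.where(np.isnan(data), MISSING, data)
        return cls(data.astype(np.int8), df.index.astype(str), df.columns)

    def to_plink_raw(self, path, pedigree=None) -> None:
        """Write the PLINK ``--recode A`` additive dosage dialect."""
        sires = dams = None
        if pedigree is not None:
            tab = pedigree.table.set_index("id")
            sires = tab["sire"].reindex(self.ids).fillna("0")
            dams = tab["dam"].reindex(self.ids).fillna("0")
        with open(path, "w") as fh:
            header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
            fh.write(" ".join(header + [f"{m}_A" for m in self.markers]) + "\n")
            for i, iid in enumerate(self.ids):
                pat = sires.iloc[i] if sires is not None else "0"
                mat = dams.iloc[i] if dams is not None else "0"
                cells = ["NA" if g == MISSING else str(int(g)) for g in self.data[i]]
                fh.write(" ".join(["0", iid, str(pat), str(mat), "0", "-9"] + cells) + "\n")

    @classmethod
    def from_plink_raw(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        markers = [c[:-2] if c.endswith("_A") else c for c in df.columns if c not in meta]
        geno_cols = [c for c in df.columns if c not in meta]
        data = df[geno_cols].to_numpy(dtype=float)
        data = np.where(np.isnan(data), MISSING, data)
        return cls(data.astype(np.int8), df["IID"].astype(str), markers)
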