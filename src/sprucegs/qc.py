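"""Genotype quality control and missing-call imputation.

Cleaning rules, applied in order: remove markers that are monomorphic,
have a call rate below 0.85, a minor allele frequency below 0.005, or
are Mendelian-impossible against both recorded parental genotypes for
any offspring; then remove individuals with call rate below 0.80;
finally impute remaining missing calls from Binomial(2, p) at the
observed post-QC allele frequencies.  All thresholds are strict: a
marker or individual sitting exactly at a threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sprucegs.genotypes import MISSING, GenotypeMatrix
from sprucegs.pedigree import Pedigree

__all__ = ["QCError", "QCReport", "filter_markers", "filter_individuals",
           "impute_missing", "run_qc"]


class QCError(ValueError):
    """Raised when quality control would remove everything."""


@dataclass
class QCReport:
    """Per-marker flags and per-individual call rates from one QC pass."""

    marker_flags: pd.DataFrame = field(default_factory=pd.DataFrame)
    individual_call_rates: pd.Series = field(default_factory=pd.Series)
    n_markers_in: int = 0
    n_markers_removed: int = 0
    n_individuals_in: int = 0
    n_individuals_removed: int = 0

    @property
    def n_markers_retained(self) -> int:
        return self.n_markers_in - self.n_markers_removed

    @property
    def n_individuals_retained(self) -> int:
        return self.n_individuals_in - self.n_individuals_removed

    def to_dict(self) -> dict:
        counts = {}
        if not self.marker_flags.empty:
            counts = {c: int(self.marker_flags[c].sum())
                      for c in self.marker_flags.columns}
        return {
            "markers_in": self.n_markers_in,
            "markers_removed": self.n_markers_removed,
            "markers_retained": self.n_markers_retained,
            "individuals_in": self.n_individuals_in,
            "individuals_removed": self.n_individuals_removed,
            "individuals_retained": self.n_individuals_retained,
            "marker_flag_counts": counts,
        }


# genotype codes an offspring may carry given an (unordered) parent pair;
# row index = sire code, column = dam code, entry = bitmask over {0,1,2}
_ALLOWED = np.array(
    [
        # dam:   0          1            2
        [0b001, 0b011, 0b010],  # sire 0
        [0b011, 0b111, 0b110],  # sire 1
        [0b010, 0b110, 0b100],  # sire 2
    ]
)


def _mendelian_violations(G: GenotypeMatrix, pedigree: Pedigree) -> np.ndarray:
    """True per marker when some offspring call is impossible given the
    joint genotypes of both its recorded (and genotyped) parents."""
    pos = {iid: k for k, iid in enumerate(G.ids)}
    trios = []
    for iid in G.ids:
        if iid not in pedigree._index:
            continue
        sire, dam = pedigree.parents_of(iid)
        if sire in pos and dam in pos:
            trios.append((pos[iid], pos[sire], pos[dam]))
    flags = np.zeros(G.n_markers, dtype=bool)
    if not trios:
        return flags
    trios = np.asarray(trios)
    child = G.data[trios[:, 0]]
    sire = G.data[trios[:, 1]]
    dam = G.data[trios[:, 2]]
    callable_ = (child != MISSING) & (sire != MISSING) & (dam != MISSING)
    allowed = _ALLOWED[np.clip(sire, 0, 2), np.clip(dam, 0, 2)]
    bad = callable_ & (((allowed >> np.clip(child, 0, 2).astype(int)) & 1) == 0)
    return bad.any(axis=0)


def filter_markers(G: GenotypeMatrix, pedigree: Pedigree | None = None,
                   call_rate_min: float = 0.85, maf_min: float = 0.005
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop failing markers; the report itemizes the reason per marker."""
    freq = G.allele_freq()
    with np.errstate(invalid="ignore"):
        monomorphic = np.isnan(freq) | (freq <= 0.0) | (freq >= 1.0)
        low_call = G.marker_call_rate() < call_rate_min
        low_maf = (G.maf() < maf_min) & ~monomorphic
    mismatch = (_mendelian_violations(G, pedigree)
                if pedigree is not None else np.zeros(G.n_markers, dtype=bool))
    flags = pd.DataFrame(
        {
            "monomorphic": monomorphic,
            "low_call_rate": low_call,
            "low_maf": low_maf,
            "parental_mismatch": mismatch,
        },
        index=pd.Index(G.markers, name="marker"),
    )
    remove = flags.any(axis=1).to_numpy()
    if remove.all():
        raise QCError("marker QC removed the entire panel")
    cleaned = G.take_markers(~remove)
    report = QCReport(
        marker_flags=flags,
        n_markers_in=G.n_markers,
        n_markers_removed=int(remove.sum()),
        n_individuals_in=G.n_individuals,
    )
    return cleaned, report


def filter_individuals(G: GenotypeMatrix, call_rate_min: float = 0.80
                       ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop individuals whose genotype call rate is below threshold."""
    rates = pd.Series(G.individual_call_rate(), index=pd.Index(G.ids, name="id"))
    remove = (rates < call_rate_min).to_numpy()
    if remove.all():
        raise QCError("individual QC removed everyone")
    cleaned = G.take_individuals(~remove)
    report = QCReport(
        individual_call_rates=rates,
        n_markers_in=G.n_markers,
        n_individuals_in=G.n_individuals,
        n_individuals_removed=int(remove.sum()),
    )
    return cleaned, report


def impute_missing(G: GenotypeMatrix, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Replace missing calls with draws from Binomial(2, p_m).

    ``p_m`` is the observed second-allele frequency at marker m; observed
    calls are never altered.  Monomorphic-with-missing columns impute
    deterministically (p of 0 or 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    data = G.data.copy()
    freq = G.allele_freq()
    miss_i, miss_m = np.nonzero(G.missing_mask)
    if miss_i.size:
        p = freq[miss_m]
        if np.isnan(p).any():
            raise QCError("cannot impute markers with no observed calls")
        data[miss_i, miss_m] = rng.binomial(2, p).astype(np.int8)
    return GenotypeMatrix(data, G.ids, G.markers)


def run_qc(G: GenotypeMatrix, pedigree: Pedigree | None = None,
           marker_call_rate_min: float = 0.85, maf_min: float = 0.005,
           individual_call_rate_min: float = 0.80, seed: int | None = None
           ) -> tuple[GenotypeMatrix, dict]:
    """Full cleaning pass: marker filters, individual filter, imputation.

    Frequencies used for imputation are recomputed on the cleaned panel.
    Returns the imputed matrix and a dict of the two stage reports.
    """
    cleaned, marker_report = filter_markers(G, pedigree, marker_call_rate_min, maf_min)
    cleaned, ind_report = filter_individuals(cleaned, individual_call_rate_min)
    imputed = impute_missing(cleaned, seed=seed)
    return imputed, {"markers": marker_report, "individuals": ind_report}
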