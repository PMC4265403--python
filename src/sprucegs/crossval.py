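"""Cross-validation of genomic prediction under relatedness scenarios.

Fold construction assigns either individuals (CV1) or whole full-sib
families (CV2, never splitting a family) to k folds of near-equal size.
Four subpopulation scenarios control the relatedness and environment
overlap between training and testing sets:

* within-BG  - train and test inside one breeding group (full sibs link
  the sets; both sites present, so G-by-E is averaged over),
* BG1 -> BG2 - train in one group, test in the genetically unrelated
  other group (all known relatedness removed),
* within-site - train and test inside one site pooling both groups,
* S1 -> S2   - train on one site, test on the other (no phenotypes from
  the testing environment).

Each of the k rounds withholds the testing fold's phenotypes, refits the
chosen prediction model on the training records, predicts the withheld
individuals, and scores the Pearson correlation between predictions and
reference breeding values (pedigree EBVs from the full data, and/or
simulated true values).  Relative efficiency is the marker-based mean
accuracy as a percentage of the pedigree-based one on identical folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sprucegs.genotypes import GenotypeMatrix
from sprucegs.markers import MarkerRegression
from sprucegs.pedigree import Pedigree
from sprucegs.polygenic import AnimalModel

__all__ = ["FoldAssignment", "Scenario", "AccuracyReport", "CVData",
           "assign_folds", "run_cv", "accuracy", "relative_efficiency"]


@dataclass
class FoldAssignment:
    """Unit -> fold map; units are individuals (CV1) or families (CV2)."""

    mode: str
    k: int
    fold_of: dict[str, int]
    seed: int | None = None

    def units_in(self, fold: int) -> list[str]:
        return [u for u, f in self.fold_of.items() if f == fold]


def assign_folds(units, k: int = 10, mode: str = "CV1",
                 seed: int | None = None) -> FoldAssignment:
    """Randomly partition units into k folds with sizes differing by <= 1."""
    units = [str(u) for u in units]
    if len(set(units)) != len(units):
        raise ValueError("units must be unique")
    if k > len(units):
        raise ValueError(f"cannot build {k} folds from {len(units)} units")
    rng = np.random.default_rng(seed)
    order = list(units)
    rng.shuffle(order)
    fold_of = {u: i % k for i, u in enumerate(order)}
    return FoldAssignment(mode=mode.upper(), k=k, fold_of=fold_of, seed=seed)


@dataclass
class Scenario:
    """Training/testing subpopulation filters.

    ``train`` and ``test`` are (column, value) pairs evaluated against
    the data's membership table (columns ``group`` and ``site``).  For
    the transfer scenarios the two filters must be disjoint.
    """

    name: str
    train: tuple[str, str]
    test: tuple[str, str]

    @classmethod
    def within(cls, column: str, value: str) -> "Scenario":
        return cls(name=value, train=(column, value), test=(column, value))

    @classmethod
    def transfer(cls, column: str, train_value: str, test_value: str) -> "Scenario":
        if train_value == test_value:
            raise ValueError("transfer scenario needs distinct subpopulations")
        return cls(name=f"{train_value}->{test_value}",
                   train=(column, train_value), test=(column, test_value))

    @property
    def is_transfer(self) -> bool:
        return self.train != self.test


@dataclass
class CVData:
    """Everything one CV run needs, aligned on individual IDs.

    ``pheno`` must already be adjusted/standardized (pooled across
    sites); ``genotypes`` complete (imputed).  ``membership`` maps each
    phenotyped individual to its breeding group and site.
    """

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    pheno: pd.DataFrame
    trait: str

    @property
    def membership(self) -> pd.DataFrame:
        m = self.pheno[["id", "site", "block"]].copy()
        m["group"] = m["id"].map(self.pedigree.groups)
        return m.set_index("id")

    def y(self, ids=None) -> pd.Series:
        s = self.pheno.set_index("id")[self.trait]
        return s if ids is None else s.reindex(ids)


@dataclass
class AccuracyReport:
    """Per-fold accuracies and their mean/SE for one model and scenario."""

    model: str
    trait: str
    scenario: str
    mode: str
    fold_accuracies: pd.DataFrame  # one column per reference
    predictions: pd.Series = field(default_factory=pd.Series)
    notes: list[str] = field(default_factory=list)

    def mean(self, reference: str = "ebv") -> float:
        return float(self.fold_accuracies[reference].mean())

    def se(self, reference: str = "ebv") -> float:
        accs = self.fold_accuracies[reference].dropna()
        return float(accs.std(ddof=1) / np.sqrt(len(accs)))

    def to_dict(self) -> dict:
        out = {"model": self.model, "trait": self.trait,
               "scenario": self.scenario, "mode": self.mode}
        for ref in self.fold_accuracies.columns:
            out[f"accuracy_{ref}"] = round(self.mean(ref), 2)
            out[f"se_{ref}"] = round(self.se(ref), 3)
        return out


def accuracy(predicted: pd.Series, reference: pd.Series) -> float:
    """Pearson correlation over intersecting IDs (NaN if undefined)."""
    joined = pd.concat([predicted, reference], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired values")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def relative_efficiency(r_marker: float, r_pedigree: float) -> float:
    """Marker accuracy as a rounded percentage of pedigree accuracy."""
    if r_pedigree == 0 or not np.isfinite(r_pedigree):
        return float("nan")
    return float(round(100.0 * r_marker / r_pedigree))


def _fit_and_predict(model: str, data: CVData, train_ids: list[str],
                     test_ids: list[str], subset, mcmc: dict, seed: int
                     ) -> pd.Series:
    y_train = data.y(train_ids).dropna()
    if model == "pedigree":
        pheno_train = data.pheno[data.pheno["id"].isin(set(y_train.index))]
        am = AnimalModel(pheno_train, data.pedigree, data.trait)
        # short per-fold chains are deliberate; skip the convergence nag
        res = am.fit(seed=seed, check_convergence=False, **mcmc)
        return res.ebv.reindex(test_ids)
    G = data.genotypes
    if subset is not None:
        G = G.select_markers(subset.markers)
    variant = {"rr": "rr", "rra": "rra", "subset-rr": "rr"}[model]
    reg = MarkerRegression(y_train, G, variant, pedigree=data.pedigree)
    res = reg.fit(seed=seed, **mcmc)
    pred = res.predict(G.select_individuals(test_ids),
                       include_polygenic=(variant == "rra"))
    return pred.reindex(test_ids)


def run_cv(scenario: Scenario, data: CVData, model: str = "rr",
           references: dict[str, pd.Series] | None = None,
           k: int = 10, mode: str = "CV1", seed: int = 0,
           subset=None, mcmc: dict | None = None) -> AccuracyReport:
    """k rounds of scenario-structured cross-validation.

    ``references`` maps labels to reference breeding values (e.g.
    ``{"ebv": full-data pedigree EBVs, "true": simulated values}``);
    accuracies are reported for every reference.  Reference EBVs are
    computed once on all data by the caller and never refit per fold -
    the leakage this implies is a documented property of the accuracy
    definition, not an accident.
    """
    if model not in ("pedigree", "rr", "rra", "subset-rr"):
        raise ValueError(f"unknown model {model!r}")
    if model == "subset-rr" and subset is None:
        raise ValueError("subset-rr requires a marker subset")
    if references is None:
        raise ValueError("provide at least one reference EBV series")
    mcmc = dict(mcmc or {})
    mcmc.setdefault("iterations", 3000)
    mcmc.setdefault("burnin", 500)
    mcmc.setdefault("thin", 5)

    memb = data.membership
    col, val = scenario.train
    train_pop = [i for i in memb.index[memb[col] == val]]
    col, val = scenario.test
    test_pop = [i for i in memb.index[memb[col] == val]]
    if scenario.is_transfer and set(train_pop) & set(test_pop):
        raise ValueError("transfer scenario subpopulations overlap")

    fam = data.pedigree.family_of()

    def fold_map(pop, fold_seed):
        if mode.upper() == "CV2":
            fams = sorted({fam[i] for i in pop if fam[i] is not None})
            fa = assign_folds(fams, k=k, mode="CV2", seed=fold_seed)
            return {i: fa.fold_of[fam[i]] for i in pop if fam[i] is not None}
        fa = assign_folds(pop, k=k, mode="CV1", seed=fold_seed)
        return fa.fold_of

    train_folds = fold_map(train_pop, seed)
    test_folds = train_folds if not scenario.is_transfer else fold_map(test_pop, seed + 1)

    rows = []
    notes = []
    predictions = []
    for fold in range(k):
        if scenario.is_transfer:
            train_ids = [i for i in train_pop if train_folds.get(i, -1) != fold]
            test_ids = [i for i in test_pop if test_folds.get(i, -1) == fold]
        else:
            train_ids = [i for i in train_pop if train_folds.get(i, -1) != fold]
            test_ids = [i for i in train_pop if train_folds.get(i, -1) == fold]
        if not test_ids:
            notes.append(f"fold {fold}: empty test set, skipped")
            warnings.warn(notes[-1])
            continue
        pred = _fit_and_predict(model, data, train_ids, test_ids, subset,
                                mcmc, seed + 1000 + fold)
        predictions.append(pred)
        row = {}
        for label, ref in references.items():
            try:
                row[label] = accuracy(pred, ref)
            except ValueError:
                row[label] = float("nan")
        rows.append(pd.Series(row, name=fold))
    fold_acc = pd.DataFrame(rows)
    # out-of-fold predictions; within-subpopulation CV covers everyone once
    pred_all = pd.concat(predictions) if predictions else pd.Series(dtype=float)
    pred_all = pred_all[~pred_all.index.duplicated(keep="first")]
    return AccuracyReport(model=model, trait=data.trait, scenario=scenario.name,
                          mode=mode.upper(), fold_accuracies=fold_acc,
                          predictions=pred_all, notes=notes)
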