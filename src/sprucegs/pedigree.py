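"""Pedigree container: a directed acyclic parent map with group labels.

Individuals are identified by string IDs; unknown parents are recorded as
missing.  The pedigree is kept in a :class:`pandas.DataFrame` with columns
``id, sire, dam, group`` and is validated (unique IDs, no cycles) on
construction.  A topological ordering (parents before offspring) is
computed once and reused by the relationship-matrix code.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown IDs)."""


class Pedigree:
    """A parent map over uniquely identified individuals.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``id``, ``sire``, ``dam`` and optionally ``group``.
        Missing parents may be given as NaN, ``None``, ``""`` or ``"0"``.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        required = {"id", "sire", "dam"}
        if not required.issubset(df.columns):
            raise PedigreeError(f"pedigree table needs columns {sorted(required)}")
        if "group" not in df.columns:
            df["group"] = "G1"
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            df[col] = df[col].where(df[col].notna(), None)
            df[col] = df[col].map(
                lambda v: None if v is None or str(v) in ("", "0", "nan") else str(v)
            )
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicated individual IDs: {dups[:5]}")
        self.table = df[["id", "sire", "dam", "group"]].reset_index(drop=True)
        self._index = {iid: i for i, iid in enumerate(self.table["id"])}
        known = set(self._index)
        for col in ("sire", "dam"):
            unknown = {p for p in self.table[col] if p is not None and p not in known}
            if unknown:
                raise PedigreeError(f"{col} IDs absent from pedigree: {sorted(unknown)[:5]}")
        self._order = self._toposort()

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("id")["group"]

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        row = self.table.iloc[self._index[iid]]
        return row["sire"], row["dam"]

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.table["sire"].isna() & self.table["dam"].isna()).to_numpy()

    @property
    def founders(self) -> list[str]:
        return list(self.table.loc[self.founder_mask, "id"])

    def family_of(self) -> pd.Series:
        """Full-sib family label per non-founder: the sorted parent pair."""
        def label(row):
            if row["sire"] is None and row["dam"] is None:
                return None
            return "x".join(sorted(str(p) for p in (row["sire"], row["dam"])))

        fam = self.table.apply(label, axis=1)
        fam.index = self.table["id"]
        return fam

    # -- structure -------------------------------------------------------

    def _toposort(self) -> np.ndarray:
        """Kahn's algorithm; raises on cycles."""
        n = len(self.table)
        sire = self.table["sire"].to_numpy()
        dam = self.table["dam"].to_numpy()
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p is not None:
                    children[self._index[p]].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle")
        return np.asarray(order, dtype=np.intp)

    @property
    def topological_order(self) -> np.ndarray:
        """Row indices such that every parent precedes its offspring."""
        return self._order

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) arrays with -1 for unknown parents."""
        def enc(col):
            return np.asarray(
                [self._index[p] if p is not None else -1 for p in self.table[col]],
                dtype=np.intp,
            )

        return enc("sire"), enc("dam")

    def relationship_classes(self) -> dict[str, list[tuple[int, int]]]:
        """Classify pairs by pedigree relationship.

        Returns index pairs (i < j) for the classes ``parent_offspring``,
        ``full_sib``, ``half_sib`` and ``unrelated`` (unrelated meaning no
        shared parent and no direct parent-offspring link; deeper kinship
        is not chased, which matches how shallow trial pedigrees are read).
        """
        sire, dam = self.parent_indices()
        n = len(self.table)
        classes: dict[str, list[tuple[int, int]]] = {
            "parent_offspring": [],
            "full_sib": [],
            "half_sib": [],
            "unrelated": [],
        }
        for i in range(n):
            for j in range(i + 1, n):
                if sire[j] == i or dam[j] == i or sire[i] == j or dam[i] == j:
                    classes["parent_offspring"].append((i, j))
                    continue
                pi = {p for p in (sire[i], dam[i]) if p >= 0}
                pj = {p for p in (sire[j], dam[j]) if p >= 0}
                shared = len(pi & pj)
                if shared >= 2:
                    classes["full_sib"].append((i, j))
                elif shared == 1:
                    classes["half_sib"].append((i, j))
                else:
                    classes["unrelated"].append((i, j))
        return classes

    # -- IO --------------------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for col in ("sire", "dam"):
            out[col] = out[col].fillna("0")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Pedigree":
        """Build from (id, sire, dam[, group]) tuples; None for unknown."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 3:
                rec = rec + ("G1",)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=["id", "sire", "dam", "group"]))
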