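"""Breeding-design pedigrees and the additive (numerator) relationship matrix.

A pedigree here is a table of individuals with sire/dam links, sex,
generation, line and full-sib family labels.  The unknown-parent token is
the literal string ``"0"`` (the common convention in pedigree files); an
individual either has both parents known or both unknown.

The additive relationship matrix A (twice the kinship/coancestry matrix)
is built with the standard tabular method, which propagates full-sib,
half-sib, cousin and inbreeding information from the parent links alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "0"

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation", "line", "family"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or infeasible designs."""


@dataclass(frozen=True)
class Cross:
    """One planned mating: a dam from one full-sib family, a sire from another."""

    dam_family: str
    sire_family: str
    cross_id: str


@dataclass
class CrossPlan:
    """A set of planned crosses; each cross founds one new full-sib family."""

    crosses: list[Cross]

    def __len__(self) -> int:
        return len(self.crosses)

    def __iter__(self):
        return iter(self.crosses)

    def dam_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.crosses:
            out[c.dam_family] = out.get(c.dam_family, 0) + 1
        return out

    def sire_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.crosses:
            out[c.sire_family] = out.get(c.sire_family, 0) + 1
        return out


def make_circulant_design(
    family_ids: Sequence[str], offsets: Sequence[int] = (1, 2, 3)
) -> CrossPlan:
    """Circulant mating plan: the dam of family *i* is crossed to sires of
    families *i+o* (mod n) for each offset *o*.

    With n families and k distinct offsets this emits n*k crosses and every
    family contributes its female to exactly k crosses and its male to
    exactly k crosses, generating maternal and paternal half-sib links
    between neighbouring families.

    Parameters
    ----------
    family_ids
        Ordered labels of the parental full-sib families (or founder pairs).
    offsets
        Distinct nonzero circulant offsets; the default ``(1, 2, 3)`` mates
        each female to males from the next three families around the circle.
    """
    family_ids = [str(f) for f in family_ids]
    offsets = list(offsets)
    if len(set(offsets)) != len(offsets) or any(o == 0 for o in offsets):
        raise PedigreeError("offsets must be distinct and nonzero")
    n = len(family_ids)
    if n <= max(abs(o) for o in offsets):
        raise PedigreeError(
            f"design infeasible: {n} families cannot support offsets {offsets}"
        )
    if len(set(family_ids)) != n:
        raise PedigreeError("family_ids must be unique")
    crosses = []
    for i, fam in enumerate(family_ids):
        for o in offsets:
            sire_fam = family_ids[(i + o) % n]
            crosses.append(
                Cross(dam_family=fam, sire_family=sire_fam, cross_id=f"{fam}x{sire_fam}")
            )
    return CrossPlan(crosses)


@dataclass
class Pedigree:
    """Validated pedigree with topological (parents-before-offspring) order.

    The backing table has columns ``id, sire, dam, sex, generation, line,
    family``; ``"0"`` marks an unknown parent.  Input row order is arbitrary:
    a topological order is computed on construction and used everywhere.
    """

    table: pd.DataFrame
    _order: list[str] = field(default_factory=list, repr=False)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PEDIGREE_COLUMNS if c not in t.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns {missing}")
        t = t[PEDIGREE_COLUMNS].copy()
        for c in ("id", "sire", "dam", "sex", "line", "family"):
            t[c] = t[c].astype(str)
        t["generation"] = t["generation"].astype(int)
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        ids = set(t["id"])
        half = (t["sire"] == UNKNOWN) != (t["dam"] == UNKNOWN)
        if half.any():
            raise PedigreeError(
                f"individual {t.loc[half, 'id'].iloc[0]!r} has half-specified parentage"
            )
        for col in ("sire", "dam"):
            known = set(t.loc[t[col] != UNKNOWN, col].unique())
            orphan = known - ids
            if orphan:
                raise PedigreeError(
                    f"{col} {next(iter(orphan))!r} is not in the pedigree"
                )
        # sex consistency: anyone used as a sire must not be recorded female, etc.
        sex = dict(zip(t["id"], t["sex"]))
        for col, expect in (("sire", "male"), ("dam", "female")):
            for p in t.loc[t[col] != UNKNOWN, col].unique():
                if sex.get(p, "unknown") not in (expect, "unknown"):
                    raise PedigreeError(
                        f"{col} {p!r} has recorded sex {sex[p]!r}, expected {expect}"
                    )
        self.table = t.reset_index(drop=True)
        self._order = self._toposort()
        self._index = {iid: k for k, iid in enumerate(self._order)}

    def _toposort(self) -> list[str]:
        t = self.table
        parents = {
            i: [p for p in (s, d) if p != UNKNOWN]
            for i, s, d in zip(t["id"], t["sire"], t["dam"])
        }
        children: dict[str, list[str]] = {i: [] for i in parents}
        indeg = {i: 0 for i in parents}
        for i, ps in parents.items():
            for p in ps:
                children[p].append(i)
                indeg[i] += 1
        # deterministic: process founders in table order, then FIFO
        from collections import deque

        queue = deque(i for i in t["id"] if indeg[i] == 0)
        order = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(parents):
            raise PedigreeError("pedigree contains a cycle")
        return order

    # ------------------------------------------------------------------ #

    @property
    def ids(self) -> list[str]:
        """Individual ids in topological order."""
        return list(self._order)

    def __len__(self) -> int:
        return len(self.table)

    def parents_of(self, iid: str) -> tuple[str, str]:
        row = self.table.set_index("id").loc[iid]
        return row["sire"], row["dam"]

    def subset_line(self, line: str, include_base: bool = True) -> "Pedigree":
        """Pedigree of one line plus (optionally) all its ancestors."""
        t = self.table
        keep = set(t.loc[t["line"] == line, "id"])
        if include_base:
            parent = dict(zip(t["id"], zip(t["sire"], t["dam"])))
            stack = list(keep)
            while stack:
                i = stack.pop()
                for p in parent[i]:
                    if p != UNKNOWN and p not in keep:
                        keep.add(p)
                        stack.append(p)
        return Pedigree(t[t["id"].isin(keep)].copy())

    # ------------------------------------------------------------------ #

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str).assign(
            generation=lambda d: d["generation"].astype(int)
        ))


def additive_relationship_matrix(ped: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Additive relationship matrix A by the tabular method.

    Returns ``(A, ids)`` with rows/columns in the pedigree's topological
    order.  Founders get A_ii = 1 and zero off-diagonals; for a non-founder
    with sire s and dam d, A_ii = 1 + 0.5*A[s, d] (1 plus the inbreeding
    coefficient) and A_ij = 0.5*(A[j, s] + A[j, d]) for every earlier j.
    """
    ids = ped.ids
    n = len(ids)
    idx = {iid: k for k, iid in enumerate(ids)}
    t = ped.table.set_index("id")
    sires = t["sire"].to_dict()
    dams = t["dam"].to_dict()
    A = np.zeros((n, n))
    for k, iid in enumerate(ids):
        s, d = sires[iid], dams[iid]
        if s == UNKNOWN:
            A[k, k] = 1.0
            continue
        si, di = idx[s], idx[d]
        A[k, k] = 1.0 + 0.5 * A[si, di]
        if k:
            row = 0.5 * (A[:k, si] + A[:k, di])
            A[:k, k] = row
            A[k, :k] = row
    return A, ids


def inbreeding_coefficients(ped: Pedigree) -> dict[str, float]:
    """F_i = A_ii - 1 for every individual."""
    A, ids = additive_relationship_matrix(ped)
    return {iid: float(A[k, k] - 1.0) for k, iid in enumerate(ids)}


def count_pair_relationships(
    ped: Pedigree, ids: Iterable[str]
) -> tuple[int, int, int]:
    """Counts of (full-sib, maternal half-sib, paternal half-sib) unordered
    pairs among ``ids``.

    Full sib: same dam and same sire.  Maternal half sib: same dam,
    different sire.  Paternal half sib: same sire, different dam.  Pairs
    with any unknown parent fall in no category.
    """
    ids = list(dict.fromkeys(str(i) for i in ids))
    if not ids:
        raise PedigreeError("ids must be nonempty")
    t = ped.table.set_index("id").loc[ids]
    known = t[(t["sire"] != UNKNOWN) & (t["dam"] != UNKNOWN)]

    def npairs(sizes: "pd.Series") -> int:
        return int((sizes * (sizes - 1) // 2).sum())

    full = npairs(known.groupby(["sire", "dam"]).size())
    same_dam = npairs(known.groupby("dam").size())
    same_sire = npairs(known.groupby("sire").size())
    return full, same_dam - full, same_sire - full


def average_relatedness(ped: Pedigree) -> float:
    """Mean of A_ij over all unordered distinct pairs in the pedigree."""
    if len(ped) < 2:
        raise PedigreeError("average relatedness undefined for < 2 individuals")
    A, _ = additive_relationship_matrix(ped)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(A[iu].mean())
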