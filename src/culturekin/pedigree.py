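"""Genetic pedigrees, coancestry and the additive relationship matrix A.

The pedigree is the genealogy of the study population: one record per
individual naming its sire and dam (either may be unknown).  From it we
compute the coefficient of coancestry ``theta_ij`` — the probability that an
allele drawn at random from individual *i* is identical by descent to one
drawn from *j* — and the additive genetic relationship matrix ``A`` with
``A_ij = 2 * theta_ij``, whose diagonal is ``1 + F_i`` where ``F_i`` is the
inbreeding coefficient.  ``A`` is the covariance structure of breeding values
in the animal model.

Two independent computational routes are provided: the O(n^2) single-pass
tabular recursion (:func:`additive_matrix`) and the pairwise recursive
coancestry (:func:`kinship_coefficient`), which serves as a slow reference
for the matrix builder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .relmatrix import RelationshipMatrix

logger = logging.getLogger(__name__)

#: file tokens interpreted as an unknown parent
MISSING_TOKENS = {"0", "", "NA", "na", "NaN", "nan", None}

UNKNOWN = None


@dataclass(frozen=True)
class Individual:
    """One pedigree record.

    ``sire``/``dam`` are ids or ``None`` for unknown; ``sex`` is one of
    ``"M"``, ``"F"``, ``"U"`` when recorded; ``generation`` is an optional
    non-negative cohort index.
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str | None = None
    generation: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be non-empty")
        if self.sire == self.id or self.dam == self.id:
            raise ValueError(f"individual {self.id!r} is its own parent")


class PedigreeError(ValueError):
    pass


class GeneticPedigree:
    """Validated, parent-first-ordered genealogy.

    Parameters
    ----------
    individuals :
        Pedigree records in any order.
    on_undeclared_parent :
        ``"insert"`` (default) silently adds a referenced-but-undeclared
        parent as a founder, with a logged warning; ``"error"`` raises.
    """

    def __init__(self, individuals: Iterable[Individual],
                 on_undeclared_parent: Literal["insert", "error"] = "insert"):
        records = list(individuals)
        ids = [r.id for r in records]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)

        # auto-insert undeclared parents as founders (standard convention)
        declared = set(ids)
        undeclared: list[str] = []
        for r in records:
            for p in (r.sire, r.dam):
                if p is not None and p not in declared:
                    declared.add(p)
                    undeclared.append(p)
        if undeclared:
            if on_undeclared_parent == "error":
                raise PedigreeError(
                    "parents referenced but never declared: "
                    + ", ".join(sorted(undeclared))
                )
            logger.warning(
                "inserted %d undeclared parents as founders: %s",
                len(undeclared), ", ".join(sorted(undeclared)),
            )
            records = [Individual(p) for p in undeclared] + records

        for r in records:
            if r.sire is not None and r.sire == r.dam:
                raise PedigreeError(
                    f"{r.sire!r} appears as both sire and dam of {r.id!r}"
                )

        self._members = self._toposort(records)
        self._index = {r.id: k for k, r in enumerate(self._members)}
        n = len(self._members)
        self._sire_idx = np.full(n, -1, dtype=int)
        self._dam_idx = np.full(n, -1, dtype=int)
        for k, r in enumerate(self._members):
            if r.sire is not None:
                self._sire_idx[k] = self._index[r.sire]
            if r.dam is not None:
                self._dam_idx[k] = self._index[r.dam]

    @staticmethod
    def _toposort(records: list[Individual]) -> list[Individual]:
        """Kahn topological sort, ties broken by input order."""
        import heapq

        pos = {r.id: k for k, r in enumerate(records)}
        by_id = {r.id: r for r in records}
        children: dict[str, list[str]] = {r.id: [] for r in records}
        indeg = {r.id: 0 for r in records}
        for r in records:
            for p in (r.sire, r.dam):
                if p is not None:
                    children[p].append(r.id)
                    indeg[r.id] += 1
        heap = [pos[i] for i, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        out: list[Individual] = []
        order_of = {k: r.id for k, r in enumerate(records)}
        while heap:
            i = order_of[heapq.heappop(heap)]
            out.append(by_id[i])
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, pos[c])
        if len(out) != len(records):
            cycle = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(
                f"pedigree contains a cycle among: {', '.join(cycle)}"
            )
        return out

    # -- accessors -----------------------------------------------------------
    @property
    def members(self) -> tuple[Individual, ...]:
        return tuple(self._members)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self._members)

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(r.id for r in self._members
                     if r.sire is None and r.dam is None)

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, i: str) -> bool:
        return i in self._index

    def parents(self, i: str) -> tuple[str | None, str | None]:
        r = self._members[self._index[i]]
        return r.sire, r.dam

    def parent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam positions in topological member order (-1 = unknown)."""
        return self._sire_idx.copy(), self._dam_idx.copy()


# ---------------------------------------------------------------------------
# coancestry / inbreeding / A
# ---------------------------------------------------------------------------

def tabular_relationship(sire_idx: np.ndarray, dam_idx: np.ndarray
                         ) -> np.ndarray:
    """Numerator relationship matrix by the single-pass tabular recursion.

    ``sire_idx``/``dam_idx`` give parent positions in a parent-first ordering
    (-1 for unknown).  Unknown parents contribute nothing, i.e. they behave
    as unique unrelated non-inbred founders.
    """
    n = len(sire_idx)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire_idx[j], dam_idx[j]
        if j > 0:
            row = np.zeros(j)
            if s >= 0:
                row += A[:j, s]
            if d >= 0:
                row += A[:j, d]
            row *= 0.5
            A[:j, j] = row
            A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def additive_matrix(ped: GeneticPedigree) -> RelationshipMatrix:
    """Additive genetic relationship matrix ``A`` (``A_ij = 2 theta_ij``)."""
    s, d = ped.parent_arrays()
    return RelationshipMatrix(ped.ids, tabular_relationship(s, d))


def kinship_coefficient(ped: GeneticPedigree, i: str, j: str) -> float:
    """Coefficient of coancestry ``theta_ij`` by the pairwise recursion.

    The recursion unrolls the later-born member of each pair onto its
    parents: ``theta_ij = (theta_{i,sire(j)} + theta_{i,dam(j)}) / 2`` and
    ``theta_ii = (1 + theta_{sire(i),dam(i)}) / 2``, with unknown parents
    contributing zero.  Quadratic per pair; kept as the reference oracle for
    :func:`additive_matrix`.
    """
    idx = {m.id: k for k, m in enumerate(ped.members)}
    for name in (i, j):
        if name not in idx:
            raise KeyError(f"unknown individual id {name!r}")
    sire, dam = ped.parent_arrays()
    memo: dict[tuple[int, int], float] = {}

    def theta(a: int, b: int) -> float:
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            s, d = sire[a], dam[a]
            f = theta(s, d) if (s >= 0 and d >= 0) else 0.0
            val = 0.5 * (1.0 + f)
        else:
            # b is later in the parent-first order, hence not an ancestor of a
            s, d = sire[b], dam[b]
            val = 0.5 * ((theta(a, s) if s >= 0 else 0.0)
                         + (theta(a, d) if d >= 0 else 0.0))
        memo[key] = val
        return val

    return theta(idx[i], idx[j])


def inbreeding(ped: GeneticPedigree) -> dict[str, float]:
    """Inbreeding coefficient ``F_i = theta(sire_i, dam_i)`` per individual.

    Zero whenever either parent is unknown.
    """
    A = additive_matrix(ped)
    return {i: float(A.values[k, k] - 1.0) for k, i in enumerate(ped.ids)}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_parent(tok: object) -> str | None:
    if tok is None or (isinstance(tok, float) and np.isnan(tok)):
        return None
    s = str(tok).strip()
    return None if s in MISSING_TOKENS else s


def read_pedigree(path: str | Path,
                  dialect: dict[str, str] | None = None,
                  on_undeclared_parent: Literal["insert", "error"] = "insert",
                  ) -> GeneticPedigree:
    """Read a delimited pedigree file (header row; comma or tab autodetected).

    ``dialect`` maps the canonical column names ``id``, ``sire``, ``dam`` to
    the file's column names; unknown parents may be encoded as ``0``, an
    empty field, or ``NA``.  Extra columns are ignored.
    """
    cols = {"id": "id", "sire": "sire", "dam": "dam"}
    if dialect:
        cols.update(dialect)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # autodetect sniffing warning
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         comment="#", skip_blank_lines=True)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise PedigreeError(
            f"pedigree file {path} lacks required columns: {missing}"
        )
    records = [
        Individual(
            id=str(row[cols["id"]]).strip(),
            sire=_parse_parent(row[cols["sire"]]),
            dam=_parse_parent(row[cols["dam"]]),
        )
        for _, row in df.iterrows()
    ]
    return GeneticPedigree(records, on_undeclared_parent=on_undeclared_parent)


def write_pedigree(ped: GeneticPedigree, path: str | Path, sep: str = "\t",
                   header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(sep.join(["id", "sire", "dam"]) + "\n")
        for r in ped.members:
            fh.write(sep.join([r.id, r.sire or "0", r.dam or "0"]) + "\n")
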