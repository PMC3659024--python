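"""Cultural pedigrees and the cultural relationship matrix C.

The cultural pedigree records who reared (and hence socially tutored) each
individual, together with the culture — the behavioral group, e.g. a song
dialect — in which it was raised.  Under natal rearing it coincides with the
genetic genealogy; cross-fostering decouples the two.

Three forms of the cultural covariance structure are supported:

1. **culture identity** — ``C_ij = 1`` iff *i* and *j* were raised in the
   same culture (a block matrix over cultures);
2. **social contacts** — a symmetrized, max-normalized matrix of pairwise
   encounter weights;
3. **cultural relatedness** — coefficients of cultural coancestry from the
   rearing links, computed by the same tabular recursion used for the
   additive genetic matrix, optionally with contact weights modulated by
   per-relation "social inertia" weights (form 3 reduces to form 2 when all
   inertia weights are one).

Form 3's recursion choice makes ``C`` identical to ``A`` when rearing links
equal genetic links — exactly the confounding that partial cross-fostering
is designed to break, quantified here by :func:`pedigree_overlap`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import (
    GeneticPedigree,
    Individual,
    PedigreeError,
    _parse_parent,
    tabular_relationship,
)
from .relmatrix import RelationshipMatrix


@dataclass(frozen=True)
class ContactRecord:
    """One observed pairwise social association (count or duration)."""

    i: str
    j: str
    weight: float
    relation_class: str | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-contact for {self.i!r}")
        if self.weight < 0:
            raise ValueError("contact weight must be non-negative")


class CulturalPedigree:
    """Rearing links plus culture labels for every individual.

    Internally reuses :class:`GeneticPedigree` validation/ordering over the
    rearing links (acyclicity, declared parents, parent-first order).
    """

    def __init__(self, individuals: Iterable[Individual],
                 cultures: Mapping[str, str],
                 genetic: GeneticPedigree | None = None,
                 cross_fostered: Mapping[str, bool] | None = None):
        self._ped = GeneticPedigree(individuals, on_undeclared_parent="error")
        self.culture = {}
        for i in self._ped.ids:
            if i not in cultures or cultures[i] in (None, ""):
                raise PedigreeError(f"missing culture label for {i!r}")
            self.culture[i] = str(cultures[i])
        if cross_fostered is not None:
            self.cross_fostered = {i: bool(cross_fostered.get(i, False))
                                   for i in self._ped.ids}
        elif genetic is not None:
            self.cross_fostered = {
                i: (i in genetic
                    and genetic.parents(i) != self._ped.parents(i))
                for i in self._ped.ids
            }
        else:
            self.cross_fostered = {i: False for i in self._ped.ids}

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ped.ids

    @property
    def members(self) -> tuple[Individual, ...]:
        return self._ped.members

    def rearing_parents(self, i: str) -> tuple[str | None, str | None]:
        return self._ped.parents(i)

    def parent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._ped.parent_arrays()

    @property
    def culture_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.culture.values())))

    def __len__(self) -> int:
        return len(self._ped)


# ---------------------------------------------------------------------------
# the three C forms
# ---------------------------------------------------------------------------

def culture_identity_matrix(cped: CulturalPedigree) -> RelationshipMatrix:
    """Form 1: ``C_ij = 1`` iff *i* and *j* share a culture (incl. i = j)."""
    labels = np.array([cped.culture[i] for i in cped.ids])
    vals = (labels[:, None] == labels[None, :]).astype(float)
    return RelationshipMatrix(cped.ids, vals)


def contact_matrix(records: Iterable[ContactRecord],
                   ids: Sequence[str],
                   inertia: Mapping[str, float] | None = None,
                   ) -> RelationshipMatrix:
    """Forms 2-3: social-encounter matrix, inertia-weighted and normalized.

    Each record contributes ``weight * inertia[relation_class]`` to the
    (i, j) cell (inertia defaults to 1 for every class, which is the plain
    contact-sum form).  The accumulated matrix is symmetrized as
    ``(S + S') / 2``, divided by its largest entry, and given a unit
    diagonal so it scales like a relative covariance structure.
    """
    ids = [str(i) for i in ids]
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    S = np.zeros((n, n))
    inertia = dict(inertia or {})
    for rec in records:
        for name in (rec.i, rec.j):
            if name not in idx:
                raise KeyError(f"contact id {name!r} absent from id list")
        w = rec.weight * inertia.get(rec.relation_class, 1.0)
        S[idx[rec.i], idx[rec.j]] += w
    S = (S + S.T) / 2.0
    top = S.max()
    if top > 0:
        S /= top
    np.fill_diagonal(S, 1.0)
    return RelationshipMatrix(tuple(ids), S)


def cultural_relatedness_matrix(cped: CulturalPedigree) -> RelationshipMatrix:
    """Form 3 (pedigree flavor): cultural coancestry over rearing links.

    Applies the additive-matrix tabular recursion with rearing sire/dam in
    place of the genetic parents.  Founders are treated as culturally
    unrelated even within a culture — between-culture sharing is carried by
    :func:`culture_identity_matrix`, keeping the two forms non-redundant.
    """
    s, d = cped.parent_arrays()
    return RelationshipMatrix(cped.ids, tabular_relationship(s, d))


# ---------------------------------------------------------------------------
# A-C overlap diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapReport:
    """How close the genetic and cultural covariance structures are.

    ``r_offdiag`` is the Pearson correlation of the strictly-lower-triangle
    entries of A and C (``None``, with ``r_defined = False``, when either
    triangle is constant and the correlation is undefined);
    ``frobenius_distance`` is ``||A - C||_F``; ``cross_fostered_fraction``
    is the share of individuals whose rearing parents differ from their
    genetic parents (``nan`` when no cultural pedigree is supplied).
    """

    r_offdiag: float | None
    r_defined: bool
    frobenius_distance: float
    cross_fostered_fraction: float


def pedigree_overlap(A: RelationshipMatrix, C: RelationshipMatrix,
                     cped: CulturalPedigree | None = None) -> OverlapReport:
    if A.ids != C.ids:
        raise ValueError("A and C must share the same id ordering")
    n = len(A)
    tril = np.tril_indices(n, k=-1)
    a, c = A.values[tril], C.values[tril]
    if n < 2 or np.ptp(a) == 0.0 or np.ptp(c) == 0.0:
        r, defined = None, False
    else:
        r = float(np.corrcoef(a, c)[0, 1])
        defined = True
    frob = float(np.linalg.norm(A.values - C.values))
    if cped is None:
        frac = float("nan")
    else:
        flags = [cped.cross_fostered[i] for i in cped.ids]
        frac = float(np.mean(flags)) if flags else 0.0
    return OverlapReport(r, defined, frob, frac)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_cultural_pedigree(path: str | Path,
                           genetic: GeneticPedigree | None = None,
                           ) -> CulturalPedigree:
    """Read columns id, rearing_sire, rearing_dam, culture (delimited text).

    When a genetic pedigree is supplied the per-individual cross-fostered
    flag is derived by comparing rearing with genetic parents.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         comment="#", skip_blank_lines=True)
    required = ["id", "rearing_sire", "rearing_dam", "culture"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(
            f"cultural pedigree file {path} lacks columns: {missing}"
        )
    records, cultures = [], {}
    for _, row in df.iterrows():
        i = str(row["id"]).strip()
        records.append(Individual(
            id=i,
            sire=_parse_parent(row["rearing_sire"]),
            dam=_parse_parent(row["rearing_dam"]),
        ))
        label = row["culture"]
        if label is None or (isinstance(label, float) and np.isnan(label)) \
                or str(label).strip() == "":
            raise PedigreeError(f"missing culture label for {i!r}")
        cultures[i] = str(label).strip()
    return CulturalPedigree(records, cultures, genetic=genetic)


def write_cultural_pedigree(cped: CulturalPedigree, path: str | Path,
                            sep: str = "\t",
                            header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(sep.join(["id", "rearing_sire", "rearing_dam", "culture"])
                 + "\n")
        for r in cped.members:
            fh.write(sep.join([r.id, r.sire or "0", r.dam or "0",
                               cped.culture[r.id]]) + "\n")


def read_contacts(path: str | Path) -> list[ContactRecord]:
    """Read a contacts file with columns i, j, weight[, class]."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    recs = []
    for _, row in df.iterrows():
        recs.append(ContactRecord(
            i=str(row["i"]), j=str(row["j"]), weight=float(row["weight"]),
            relation_class=(str(row["class"])
                            if "class" in df.columns
                            and not pd.isna(row["class"]) else None),
        ))
    return recs
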