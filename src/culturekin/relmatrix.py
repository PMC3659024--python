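"""Individual-by-individual relationship (covariance-structure) matrices.

A :class:`RelationshipMatrix` couples an ordered list of individual ids with a
symmetric positive-semidefinite matrix of relatedness coefficients.  It is the
common currency between the pedigree builders (additive genetic matrix ``A``,
cultural matrix ``C`` and derived interaction structures) and the mixed-model
fitter, which uses it as the covariance structure of a random effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: jitter added to the diagonal when a Cholesky factorization fails; the
#: matrices produced by pedigree recursions are PSD in exact arithmetic, so
#: only rounding error ever needs absorbing.
PSD_EPSILON = 1e-8

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric PSD matrix of pairwise relatedness, indexed by individual id."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(
                f"matrix shape {vals.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in RelationshipMatrix")
        if not np.allclose(vals, vals.T, atol=_SYM_TOL):
            raise ValueError("relationship matrix is not symmetric")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "values", vals)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        idx = self.index
        return float(self.values[idx[str(i)], idx[str(j)]])

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Restrict (and reorder) to the given ids."""
        idx = self.index
        try:
            sel = np.array([idx[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not present in matrix") from exc
        return RelationshipMatrix(tuple(str(i) for i in ids),
                                  self.values[np.ix_(sel, sel)])

    # -- numerical helpers ---------------------------------------------------
    def cholesky(self, epsilon: float = PSD_EPSILON) -> np.ndarray:
        """Lower Cholesky factor, stabilized with ``epsilon * I`` if needed.

        Raises ``np.linalg.LinAlgError`` if the matrix is indefinite beyond
        the documented jitter.
        """
        try:
            return np.linalg.cholesky(self.values)
        except np.linalg.LinAlgError:
            return np.linalg.cholesky(
                self.values + epsilon * np.eye(len(self))
            )

    def is_psd(self, epsilon: float = PSD_EPSILON) -> bool:
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        return bool(w.min() >= -epsilon * max(1.0, w.max()))

    def allclose(self, other: "RelationshipMatrix", atol: float = 0.0) -> bool:
        return self.ids == other.ids and np.allclose(
            self.values, other.values, atol=atol, rtol=0.0
        )

    # -- text I/O -----------------------------------------------------------
    def to_dense(self, path: str | Path, sep: str = "\t") -> None:
        df = pd.DataFrame(self.values, index=list(self.ids),
                          columns=list(self.ids))
        df.to_csv(path, sep=sep, index_label="id")

    def to_triplet(self, path: str | Path, sep: str = "\t") -> None:
        """Sparse lower-triangle triplet output (id_i, id_j, value), j <= i."""
        rows = []
        for i in range(len(self)):
            for j in range(i + 1):
                v = self.values[i, j]
                if v != 0.0:
                    rows.append((self.ids[i], self.ids[j], v))
        pd.DataFrame(rows, columns=["id_i", "id_j", "value"]).to_csv(
            path, sep=sep, index=False
        )

    @classmethod
    def from_dense(cls, path: str | Path, sep: str | None = None
                   ) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(tuple(df.index), df.to_numpy(dtype=float))

    @classmethod
    def from_triplet(cls, path: str | Path, ids: Iterable[str] | None = None,
                     sep: str | None = None) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep=sep, engine="python",
                         dtype={"id_i": str, "id_j": str})
        if ids is None:
            seen: dict[str, None] = {}
            for col in ("id_i", "id_j"):
                for v in df[col]:
                    seen.setdefault(str(v))
            ids = list(seen)
        ids = [str(i) for i in ids]
        idx = {v: k for k, v in enumerate(ids)}
        vals = np.zeros((len(ids), len(ids)))
        for i, j, v in zip(df["id_i"], df["id_j"], df["value"]):
            vals[idx[i], idx[j]] = v
            vals[idx[j], idx[i]] = v
        return cls(tuple(ids), vals)


def identity_matrix(ids: Sequence[str]) -> RelationshipMatrix:
    return RelationshipMatrix(tuple(str(i) for i in ids),
                              np.eye(len(ids)))
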