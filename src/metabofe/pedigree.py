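"""Pedigree container and the numerator relationship matrix.

A pedigree is a table of (animal, sire, dam, generation) records with a single
sentinel (``"0"``) for unknown parents.  The additive (numerator) relationship
matrix A is built with the tabular method: processing animals so that parents
precede offspring,

    A_ii = 1 + 0.5 * A[sire, dam]          (0 when either parent is unknown)
    A_ij = 0.5 * (A[j, sire_i] + A[j, dam_i])   for j before i,

which yields twice the coancestry (kinship) matrix, with per-animal inbreeding
coefficients F_i = A_ii - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PedigreeError

UNKNOWN_PARENT = "0"


@dataclass
class Pedigree:
    """Ordered pedigree records.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``animal``, ``sire``, ``dam``, ``generation`` (extra columns
        such as ``line`` and ``sex`` are carried through untouched).  Rows must
        be topologically ordered: every named parent appears as an animal in an
        earlier row.  Unknown parents use the sentinel ``"0"``.
    """

    df: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        required = {"animal", "sire", "dam", "generation"}
        missing = required - set(self.df.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        df = self.df.copy()
        for col in ("animal", "sire", "dam"):
            df[col] = df[col].astype(str)
        self.df = df.reset_index(drop=True)
        animals = self.df["animal"].tolist()
        if UNKNOWN_PARENT in animals:
            raise PedigreeError(f"animal id equals the unknown-parent sentinel {UNKNOWN_PARENT!r}")
        if len(set(animals)) != len(animals):
            dup = self.df["animal"][self.df["animal"].duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")
        self._index = {a: i for i, a in enumerate(animals)}
        for i, (s, d) in enumerate(zip(self.df["sire"], self.df["dam"])):
            for parent in (s, d):
                if parent == UNKNOWN_PARENT:
                    continue
                j = self._index.get(parent)
                if j is None:
                    raise PedigreeError(
                        f"animal {animals[i]!r} references unknown parent {parent!r}"
                    )
                if j >= i:
                    raise PedigreeError(
                        f"parent {parent!r} of {animals[i]!r} does not precede it; "
                        "pedigree is not topologically ordered (possible cycle)"
                    )

    @property
    def animals(self) -> list[str]:
        return self.df["animal"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def index_of(self, animal: str) -> int:
        try:
            return self._index[str(animal)]
        except KeyError:
            raise PedigreeError(f"animal {animal!r} not in pedigree") from None

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of sire/dam row indices, -1 for unknown."""
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.df["sire"], self.df["dam"])):
            if s != UNKNOWN_PARENT:
                out[i, 0] = self._index[s]
            if d != UNKNOWN_PARENT:
                out[i, 1] = self._index[d]
        return out

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
        return cls(df)

    def to_csv(self, path) -> None:
        cols = ["animal", "sire", "dam", "generation"]
        self.df[cols].to_csv(path, index=False)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A with its animal ordering."""

    animals: list[str]
    a: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F = diag(A) - 1."""
        return np.diag(self.a) - 1.0

    def submatrix(self, animals) -> np.ndarray:
        """A restricted to (and ordered by) the given animals."""
        index = {a: i for i, a in enumerate(self.animals)}
        try:
            idx = np.array([index[str(a)] for a in animals])
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in relationship matrix") from None
        return self.a[np.ix_(idx, idx)]


def build_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Runs in O(n^2) with vectorized row updates; symmetric by construction.
    """
    n = len(pedigree)
    parents = pedigree.parent_indices()
    a = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        row_s = a[s, :i] if s >= 0 else 0.0
        row_d = a[d, :i] if d >= 0 else 0.0
        if s >= 0 or d >= 0:
            a[i, :i] = 0.5 * (np.asarray(row_s) + np.asarray(row_d))
            a[:i, i] = a[i, :i]
        a_sd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * a_sd
    return RelationshipMatrix(animals=pedigree.animals, a=a)
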