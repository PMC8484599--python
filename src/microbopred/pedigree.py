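"""Pedigree handling and the additive (numerator) relationship matrix.

The numerator relationship matrix ``A`` holds the expected additive-genetic
relationships between animals, computed recursively from pedigree records by
the tabular method.  Unknown parents (coded 0) are treated as unrelated,
non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "validate_pedigree",
    "numerator_relationship",
]

UNKNOWN = 0


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """Pedigree records: one (animal, sire, dam) triple per animal.

    Parents are coded by animal id; ``0`` marks an unknown parent.
    ``records`` is a DataFrame with integer columns ``animal``, ``sire``,
    ``dam`` in an arbitrary order; use :func:`validate_pedigree` to obtain a
    topologically sorted copy.
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam"}
        if not required.issubset(self.records.columns):
            raise PedigreeError(f"pedigree needs columns {sorted(required)}")
        self.records = self.records[["animal", "sire", "dam"]].astype(int)

    @property
    def animals(self) -> np.ndarray:
        return self.records["animal"].to_numpy()

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column TSV pedigree (animal, sire, dam; 0 = unknown)."""
    df = pd.read_csv(path, sep="\t")
    return Pedigree(df)


def validate_pedigree(pedigree: Pedigree) -> Pedigree:
    """Check structural validity and return a topologically sorted copy.

    Ensures unique animal ids, parents that are either unknown or present in
    the pedigree, and the absence of ancestry cycles (no animal is its own
    ancestor).  The returned pedigree lists every parent before its
    offspring.

    Raises
    ------
    PedigreeError
        On duplicate ids, a parent id absent from the pedigree, or a cycle
        (the error message names the offending ids).
    """
    df = pedigree.records
    animals = df["animal"].to_numpy()
    if len(np.unique(animals)) != len(animals):
        dupes = df["animal"][df["animal"].duplicated()].tolist()
        raise PedigreeError(f"duplicate animal ids: {dupes}")
    known = set(animals)
    for col in ("sire", "dam"):
        missing = set(df[col]) - known - {UNKNOWN}
        if missing:
            raise PedigreeError(f"{col} ids absent from pedigree: {sorted(missing)}")

    # Kahn-style topological sort on the parent -> offspring DAG.
    parents = {row.animal: (row.sire, row.dam) for row in df.itertuples()}
    order: list[int] = []
    state: dict[int, int] = {}  # 0 unvisited, 1 in progress, 2 done

    def visit(a: int, stack: list[int]) -> None:
        if state.get(a, 0) == 2 or a == UNKNOWN:
            return
        if state.get(a, 0) == 1:
            cycle = stack[stack.index(a):] + [a]
            raise PedigreeError(f"ancestry cycle: {cycle}")
        state[a] = 1
        stack.append(a)
        for p in parents[a]:
            visit(p, stack)
        stack.pop()
        state[a] = 2
        order.append(a)

    for a in animals:
        visit(int(a), [])

    sorted_df = df.set_index("animal").loc[order].reset_index()
    return Pedigree(sorted_df)


def numerator_relationship(
    pedigree: Pedigree, ids: np.ndarray | list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Numerator relationship matrix A by the tabular method.

    For each animal *i* with parents *s*, *d* (processed parents-first)::

        A[i, j] = (A[j, s] + A[j, d]) / 2      for previously processed j
        A[i, i] = 1 + A[s, d] / 2

    with unknown parents contributing 0.  Founders are unrelated and
    non-inbred.

    Parameters
    ----------
    pedigree
        Pedigree; validated and sorted internally.
    ids
        Optional subset of animal ids; the corresponding submatrix of A is
        returned in the given order.

    Returns
    -------
    (A, ids_out)
        Dense symmetric matrix and the animal ids labelling its rows.
    """
    ped = validate_pedigree(pedigree)
    animals = ped.animals
    n = len(animals)
    pos = {int(a): i for i, a in enumerate(animals)}
    A = np.zeros((n, n))
    sires = ped.records["sire"].to_numpy()
    dams = ped.records["dam"].to_numpy()
    for i in range(n):
        s, d = int(sires[i]), int(dams[i])
        si = pos.get(s, -1)
        di = pos.get(d, -1)
        row = np.zeros(i)
        if si >= 0:
            row += A[si, :i]
        if di >= 0:
            row += A[di, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        asd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    if ids is None:
        return A, animals
    idx = np.array([pos[int(a)] for a in ids])
    return A[np.ix_(idx, idx)], np.asarray(ids)


def inbreeding(pedigree: Pedigree) -> pd.Series:
    """Per-animal inbreeding coefficients F = diag(A) - 1."""
    A, ids = numerator_relationship(pedigree)
    return pd.Series(np.diag(A) - 1.0, index=ids, name="F")
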