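"""Pedigree handling and the numerator relationship matrix A.

The numerator relationship matrix holds expected additive genetic
relationships between animals implied by the pedigree.  It is built with
the tabular method (recursing over a parents-before-offspring ordering),
its inverse with Henderson's rules using Mendelian-sampling variances
derived from the inbreeding coefficients found on the diagonal of A.
All matrices are dense; the package targets desk-scale pedigrees (up to
a few thousand animals), not national evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1
#: Values in a pedigree file that denote an unknown parent.
UNKNOWN_CODES = {"0", "", ".", "NA", "nan", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class Pedigree:
    """Ordered parentage records.

    Animals are opaque string ids.  ``sire`` and ``dam`` are integer
    positions into ``animals`` (``-1`` for an unknown parent).  The
    ordering invariant — every parent appears before its offspring — is
    verified on construction.
    """

    animals: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.animals)
        if len(set(self.animals)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("parent arrays do not match animal count")
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and not (0 <= p < i):
                    raise PedigreeError(
                        f"pedigree not ordered: row {i} ({self.animals[i]!r}) "
                        f"references parent at row {p}; parents must precede offspring"
                    )
        self.index = {a: i for i, a in enumerate(self.animals)}

    def __len__(self) -> int:
        return len(self.animals)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def founders(self) -> list[str]:
        mask = (self.sire == UNKNOWN) & (self.dam == UNKNOWN)
        return [a for a, m in zip(self.animals, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        def name(p: int) -> str:
            return "0" if p == UNKNOWN else self.animals[p]

        return pd.DataFrame(
            {
                "animal": self.animals,
                "sire": [name(s) for s in self.sire],
                "dam": [name(d) for d in self.dam],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reorder: bool = False) -> "Pedigree":
        """Build a pedigree from an (animal, sire, dam) table.

        With ``reorder=True`` an unordered table is topologically sorted
        first (parents before offspring); a cycle raises.
        """
        df = df.astype(str)
        animals = list(df["animal"])
        if reorder:
            order = _toposort(animals, list(df["sire"]), list(df["dam"]))
            df = df.iloc[order].reset_index(drop=True)
            animals = list(df["animal"])
        idx = {a: i for i, a in enumerate(animals)}

        def code(p: str) -> int:
            if p in UNKNOWN_CODES:
                return UNKNOWN
            if p not in idx:
                raise PedigreeError(f"parent {p!r} has no pedigree row of its own")
            return idx[p]

        sire = np.array([code(p) for p in df["sire"]], dtype=np.int64)
        dam = np.array([code(p) for p in df["dam"]], dtype=np.int64)
        return cls(animals, sire, dam)

    @classmethod
    def from_csv(cls, path, reorder: bool = False) -> "Pedigree":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_frame(df[["animal", "sire", "dam"]], reorder=reorder)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _toposort(animals: list[str], sires: list[str], dams: list[str]) -> list[int]:
    idx = {a: i for i, a in enumerate(animals)}
    parents = []
    for s, d in zip(sires, dams):
        row = []
        for p in (s, d):
            if p not in UNKNOWN_CODES:
                if p not in idx:
                    raise PedigreeError(f"parent {p!r} has no pedigree row of its own")
                row.append(idx[p])
        parents.append(row)
    order: list[int] = []
    state = np.zeros(len(animals), dtype=np.int8)  # 0 new, 1 visiting, 2 done

    def visit(i: int) -> None:
        stack = [(i, iter(parents[i]))]
        state[i] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state[p] == 1:
                    raise PedigreeError(
                        f"pedigree cycle involving {animals[node]!r}"
                    )
                if state[p] == 0:
                    state[p] = 1
                    stack.append((p, iter(parents[p])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                order.append(node)
                stack.pop()

    for i in range(len(animals)):
        if state[i] == 0:
            visit(i)
    return order


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix over an ordered animal set."""

    values: np.ndarray
    ids: list[str]
    role: str  # one of {"A", "A_inverse", "A22", "A22_inverse", "G", "H_inverse"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimensions do not match id set")
        if n and not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"ids not present in matrix: {missing}")
        take = np.array([pos[a] for a in ids], dtype=np.int64)
        return RelationshipMatrix(self.values[np.ix_(take, take)], list(ids), self.role)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + a_(s,d)/2 and a_ij = (a_js + a_jd)/2 for j < i, with an
    unknown parent contributing zero relationship and no inbreeding.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        row = np.zeros(i)
        if s[i] != UNKNOWN:
            row += 0.5 * A[s[i], :i]
        if d[i] != UNKNOWN:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s[i], d[i]] if (s[i] != UNKNOWN and d[i] != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return RelationshipMatrix(A, list(ped.animals), "A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F = diag(A) - 1."""
    return np.diag(build_A(ped).values) - 1.0


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Inverse of A by Henderson's rules, accounting for inbreeding.

    The Mendelian-sampling variance of animal i is
    ``0.5 - 0.25 (F_s + F_d)`` with a missing parent entering as an
    unrelated, non-inbred base animal contributing 0.25 instead of
    ``0.25 (1 + F)``.
    """
    n = len(ped)
    F = inbreeding(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        par = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        m = 1.0 - sum(0.25 * (1.0 + F[p]) for p in par)
        alpha = 1.0 / m
        Ainv[i, i] += alpha
        for p in par:
            Ainv[i, p] -= 0.5 * alpha
            Ainv[p, i] -= 0.5 * alpha
        for p in par:
            for q in par:
                Ainv[p, q] += 0.25 * alpha
    return RelationshipMatrix(Ainv, list(ped.animals), "A_inverse")


def extract_A22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in the stated order."""
    pos = {a: i for i, a in enumerate(A.ids)}
    missing = [g for g in genotyped_ids if g not in pos]
    if missing:
        raise KeyError(f"genotyped ids not in pedigree: {missing}")
    take = np.array([pos[g] for g in genotyped_ids], dtype=np.int64)
    return RelationshipMatrix(
        A.values[np.ix_(take, take)], list(genotyped_ids), "A22"
    )


def prune_pedigree(ped: Pedigree, keep_ids) -> Pedigree:
    """Ancestor closure: retain ``keep_ids`` and all their ancestors.

    Used to drop pedigree branches carrying neither phenotype nor
    genotype information.  Idempotent; ordering is preserved.
    """
    keep = np.zeros(len(ped), dtype=bool)
    for a in keep_ids:
        if a in ped.index:
            keep[ped.index[a]] = True
    # walk from the bottom: a kept animal marks its parents
    for i in range(len(ped) - 1, -1, -1):
        if keep[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN:
                    keep[p] = True
    old_to_new = -np.ones(len(ped), dtype=np.int64)
    old_to_new[keep] = np.arange(int(keep.sum()))

    def remap(p: np.ndarray) -> np.ndarray:
        out = np.where(p == UNKNOWN, UNKNOWN, old_to_new[np.where(p == UNKNOWN, 0, p)])
        return out

    animals = [a for a, k in zip(ped.animals, keep) if k]
    return Pedigree(animals, remap(ped.sire[keep]), remap(ped.dam[keep]))
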