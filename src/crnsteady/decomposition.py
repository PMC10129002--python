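"""Finest independent decomposition of a reaction network.

A partition of the reaction set is *independent* when the stoichiometric
ranks of the induced subnetworks sum to the rank of the whole network; the
positive steady-state set of the whole mass-action system is then exactly
the intersection of the subnetworks' steady-state sets.  The *finest*
independent decomposition is the independent partition with the maximum
number of classes; it is unique (up to labels) and is computed here by the
coordinate-free linear algebra method: scan the reaction vectors once,
collecting a maximal linearly independent set, each basis vector seeding
its own class; every dependent vector has a unique representation in that
basis, and all classes owning a basis vector appearing with a non-zero
coefficient are merged, the dependent reaction joining the merged class.

All arithmetic is exact (rationals); zero tests are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .core import CRN, reaction_vector

__all__ = [
    "Decomposition",
    "is_independent",
    "finest_independent_decomposition",
    "subnetwork",
]


@dataclass(frozen=True)
class Decomposition:
    """A partition of reaction indices with per-class stoichiometric ranks."""

    classes: tuple[tuple[int, ...], ...]
    ranks: tuple[int, ...]
    total_rank: int

    @property
    def independent(self) -> bool:
        return sum(self.ranks) == self.total_rank

    def __len__(self) -> int:
        return len(self.classes)

    def reaction_ids(self, crn: CRN) -> list[list[str]]:
        return [[crn.reactions[i].id for i in cls] for cls in self.classes]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller representative for determinism
            lo, hi = (ra, rb) if ra < rb else (rb, ra)
            self.parent[hi] = lo
            return lo
        return ra


def _exact_rank(vectors: Sequence[Sequence[int]]) -> int:
    """Rank of a list of integer vectors by fraction-free Gaussian elimination."""
    rows = [[Fraction(v) for v in vec] for vec in vectors]
    rank = 0
    ncols = len(rows[0]) if rows else 0
    col = 0
    r = 0
    while r < len(rows) and col < ncols:
        piv = next((i for i in range(r, len(rows)) if rows[i][col] != 0), None)
        if piv is None:
            col += 1
            continue
        rows[r], rows[piv] = rows[piv], rows[r]
        pv = rows[r][col]
        for i in range(r + 1, len(rows)):
            if rows[i][col] != 0:
                f = rows[i][col] / pv
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        r += 1
        rank += 1
        col += 1
    return rank


def is_independent(crn: CRN, classes: Sequence[Sequence[int]]) -> bool:
    """True iff the per-class stoichiometric ranks sum to the whole rank.

    Raises ValueError when ``classes`` is not a partition of the reaction
    index set.
    """
    flat = sorted(i for cls in classes for i in cls)
    if flat != list(range(len(crn.reactions))):
        raise ValueError("classes do not partition the reaction index set")
    vecs = [reaction_vector(r, crn.species) for r in crn.reactions]
    total = _exact_rank(vecs)
    return sum(_exact_rank([vecs[i] for i in cls]) for cls in classes) == total


def finest_independent_decomposition(crn: CRN) -> Decomposition:
    """Compute the finest independent decomposition.

    Deterministic given reaction order; permuting the input reactions can
    relabel classes but never changes the partition itself.
    """
    if not crn.reactions:
        raise ValueError("network has no reactions")
    vecs = [
        [Fraction(v) for v in reaction_vector(r, crn.species)]
        for r in crn.reactions
    ]
    m = len(vecs)
    uf = _UnionFind(m)

    # Greedily collected maximal independent set of reaction vectors.  Each
    # basis vector seeds its own class; dependent vectors are expressed in
    # the *original* basis vectors (unique representation) and merge every
    # class whose basis vector appears with a non-zero coefficient.
    basis_vecs: list[list[Fraction]] = []
    basis_owner: list[int] = []

    for idx, vec in enumerate(vecs):
        coeffs = _representation(vec, basis_vecs)
        if coeffs is None:
            basis_vecs.append(list(vec))
            basis_owner.append(idx)
        else:
            root = idx
            for j, c in enumerate(coeffs):
                if c != 0:
                    root = uf.union(root, basis_owner[j])
    classes_map: dict[int, list[int]] = {}
    for i in range(m):
        classes_map.setdefault(uf.find(i), []).append(i)
    classes = tuple(
        tuple(sorted(v)) for _, v in sorted(classes_map.items(), key=lambda kv: min(kv[1]))
    )
    int_vecs = [reaction_vector(r, crn.species) for r in crn.reactions]
    ranks = tuple(_exact_rank([int_vecs[i] for i in cls]) for cls in classes)
    total = _exact_rank(int_vecs)
    dec = Decomposition(classes=classes, ranks=ranks, total_rank=total)
    assert dec.independent, "finest decomposition must be independent"
    return dec


def _representation(
    vec: Sequence[Fraction], basis_vecs: list[list[Fraction]]
) -> list[Fraction] | None:
    """Coefficients of ``vec`` in the original basis vectors, or None.

    Returns the unique exact coefficient list when ``vec`` lies in the span
    of ``basis_vecs`` (which are linearly independent), and None otherwise.
    Solved by Gaussian elimination on the augmented system ``B^T c = vec``.
    """
    r = len(basis_vecs)
    if r == 0:
        return None if any(v != 0 for v in vec) else []
    ncols = len(vec)
    # rows: one per species coordinate; columns: r coefficients + rhs
    aug = [[basis_vecs[j][i] for j in range(r)] + [vec[i]] for i in range(ncols)]
    pivots: list[tuple[int, int]] = []
    row = 0
    for col in range(r):
        piv = next((i for i in range(row, ncols) if aug[i][col] != 0), None)
        if piv is None:
            continue
        aug[row], aug[piv] = aug[piv], aug[row]
        pv = aug[row][col]
        for i in range(ncols):
            if i != row and aug[i][col] != 0:
                f = aug[i][col] / pv
                aug[i] = [a - f * b for a, b in zip(aug[i], aug[row])]
        pivots.append((row, col))
        row += 1
    # inconsistent system => vec is independent of the basis
    for i in range(row, ncols):
        if aug[i][r] != 0:
            return None
    coeffs = [Fraction(0)] * r
    for prow, pcol in pivots:
        coeffs[pcol] = aug[prow][r] / aug[prow][pcol]
    return coeffs


def subnetwork(crn: CRN, cls: Sequence[int]) -> CRN:
    """The CRN induced by a non-empty set of reaction indices.

    Species are restricted to those occurring in the selected reactions,
    keeping the parent network's species order.
    """
    cls = sorted(set(cls))
    if not cls:
        raise ValueError("empty reaction class")
    reactions = [crn.reactions[i] for i in cls]
    used = {s for r in reactions for s in (*r.source.species, *r.product.species)}
    species = tuple(s for s in crn.species if s in used)
    return CRN(species, reactions)
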