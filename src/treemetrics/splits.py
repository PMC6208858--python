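"""Split decomposition: isolation indices and d-split enumeration.

Every bipartition ``A | B`` of the taxon set has an *isolation index*

    alpha(A|B) = 1/2 * min over i,j in A and k,l in B of
                 ( max{ d(i,j)+d(k,l), d(i,k)+d(j,l), d(i,l)+d(j,k) }
                   - d(i,j) - d(k,l) )

(with ``i = j`` and ``k = l`` allowed, ``d(i,i) = 0``).  Splits with a
positive index (*d-splits*) are the supported bipartitions of the data; for
an additive metric they are exactly the splits induced by the tree's edges
and their indices equal the edge lengths.  The enumeration here is brute
force over all bipartitions and is intended for desk-scale taxon sets
(``n <= 16``); neighbor joining in :mod:`treemetrics.tree` is the scalable
route to an additive fit.

:func:`split_decomposition_metric` sums the pairwise-compatible d-splits
(greedy by decreasing index) into a tree metric, giving the second
additive-fit operator next to neighbor joining.  Weakly compatible splits
beyond pairwise compatibility are still *reported* by :func:`all_dsplits`;
they are only excluded from the metric so that its output is always
tree-realisable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable

import numpy as np

from .matrix import DEFAULT_TOL, DistanceMatrix

__all__ = [
    "SplitRecord",
    "quartet_isolation",
    "isolation_index",
    "all_dsplits",
    "split_decomposition_metric",
    "splits_compatible",
]

MAX_ENUM_TAXA = 16


@dataclass(frozen=True)
class SplitRecord:
    """A bipartition of the taxon set with its isolation index (distance
    units).  ``side_a`` holds the lexicographically smallest taxon."""

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    alpha: float

    def __post_init__(self):
        a, b = set(self.side_a), set(self.side_b)
        if not a or not b or (a & b):
            raise ValueError("sides must be disjoint and non-empty")

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    def side_of(self, anchor_free: bool = True) -> frozenset:
        """The side not containing the smallest label (for set comparisons)."""
        return frozenset(self.side_b)


def quartet_isolation(
    D: DistanceMatrix, pair_in: tuple[str, str], pair_out: tuple[str, str]
) -> float:
    """Isolation index of the quartet split ``{i,j} | {k,l}``:
    half the excess of the maximal pair sum over the split's own pair sum
    (0 when the split's pairing is itself maximal)."""
    i, j = pair_in
    k, l = pair_out
    if len({i, j, k, l}) != 4:
        raise ValueError("quartet labels must be distinct")
    s_own = D.get(i, j) + D.get(k, l)
    s2 = D.get(i, k) + D.get(j, l)
    s3 = D.get(i, l) + D.get(j, k)
    return max(0.0, 0.5 * (max(s_own, s2, s3) - s_own))


def isolation_index(D: DistanceMatrix, A: Iterable[str], B: Iterable[str]) -> float:
    """Isolation index of the bipartition ``A | B`` (which must partition the
    taxon set).  Reduces to :func:`quartet_isolation` when both sides have
    two taxa; degenerate quartets with repeated taxa are included, as the
    definition requires."""
    A = sorted(A)
    B = sorted(B)
    if set(A) | set(B) != set(D.labels) or set(A) & set(B) or not A or not B:
        raise ValueError("A and B must form a bipartition of the taxon set")
    ia = np.array([D.index(x) for x in A], dtype=np.intp)
    ib = np.array([D.index(x) for x in B], dtype=np.intp)
    return _isolation_from_indices(D.values, ia, ib)


def _isolation_from_indices(v: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    pa = np.array(list(combinations_with_replacement(ia, 2)), dtype=np.intp)
    pb = np.array(list(combinations_with_replacement(ib, 2)), dtype=np.intp)
    i, j = pa[:, 0][:, None], pa[:, 1][:, None]
    k, l = pb[:, 0][None, :], pb[:, 1][None, :]
    s_own = v[i, j] + v[k, l]
    s2 = v[i, k] + v[j, l]
    s3 = v[i, l] + v[j, k]
    alpha = 0.5 * (np.maximum(s_own, np.maximum(s2, s3)) - s_own)
    return float(max(alpha.min(), 0.0))


def all_dsplits(D: DistanceMatrix, tol: float = DEFAULT_TOL) -> list[SplitRecord]:
    """All bipartitions with isolation index above ``tol``, sorted by
    decreasing index (lexicographic tie-break on the sides).

    Brute-force enumeration of the ``2**(n-1) - 1`` bipartitions; capped at
    ``n <= 16`` taxa.  For an additive metric the result is exactly the
    generating tree's edge splits with indices equal to edge lengths.
    """
    n = D.n
    if n > MAX_ENUM_TAXA:
        raise ValueError(
            f"split enumeration is capped at {MAX_ENUM_TAXA} taxa (got {n}); "
            "use neighbor joining for larger inputs"
        )
    labels = D.labels
    order = sorted(range(n), key=lambda i: labels[i])
    anchor = order[0]
    rest = [i for i in order if i != anchor]
    v = D.values
    records = []
    for mask in range(1, 2 ** (n - 1)):
        in_b = [rest[t] for t in range(n - 1) if mask >> t & 1]
        in_a = [anchor] + [i for i in rest if i not in in_b]
        alpha = _isolation_from_indices(
            v, np.array(in_a, dtype=np.intp), np.array(in_b, dtype=np.intp)
        )
        if alpha > tol:
            records.append(
                SplitRecord(
                    tuple(sorted(labels[i] for i in in_a)),
                    tuple(sorted(labels[i] for i in in_b)),
                    alpha,
                )
            )
    records.sort(key=lambda r: (-r.alpha, r.side_a, r.side_b))
    return records


def splits_compatible(s1: SplitRecord, s2: SplitRecord) -> bool:
    """Two splits are (pairwise) compatible iff some pair of opposite sides
    is disjoint — exactly when both can be edges of one tree."""
    a1, b1 = set(s1.side_a), set(s1.side_b)
    a2, b2 = set(s2.side_a), set(s2.side_b)
    return not (a1 & a2) or not (a1 & b2) or not (b1 & a2) or not (b1 & b2)


def split_decomposition_metric(
    D: DistanceMatrix, tol: float = DEFAULT_TOL
) -> DistanceMatrix:
    """Additive metric from the pairwise-compatible part of the split
    decomposition.

    Splits are admitted greedily by decreasing isolation index (lexicographic
    tie-break), keeping only those compatible with everything already kept;
    the output is the weighted sum of the kept split pseudometrics.  Additive
    inputs are reproduced exactly, making this an additive-fit operator.
    """
    if D.n == 2:
        return D
    records = all_dsplits(D, tol=tol)
    kept: list[SplitRecord] = []
    for rec in records:
        if all(splits_compatible(rec, other) for other in kept):
            kept.append(rec)
    n = D.n
    pos = {lab: i for i, lab in enumerate(D.labels)}
    out = np.zeros((n, n))
    for rec in kept:
        ia = [pos[l] for l in rec.side_a]
        ib = [pos[l] for l in rec.side_b]
        out[np.ix_(ia, ib)] += rec.alpha
        out[np.ix_(ib, ia)] += rec.alpha
    return DistanceMatrix(D.labels, out)
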