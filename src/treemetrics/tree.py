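"""Unrooted edge-weighted trees, neighbor joining, and tree comparison.

:class:`PhyloTree` is a minimal unrooted tree over labeled leaves with
nonnegative edge lengths; the path metric between its leaves is an additive
metric by construction.  :func:`neighbor_joining` is a from-scratch
Saitou–Nei implementation used as the default additive-fit operator: it is
consistent (an additive input reproduces its generating tree exactly,
topology and lengths) and deterministic (ties in the Q criterion are broken
by the lexicographically smallest pair of cluster labels).

:func:`fit_additive_metric` is the projection-style operator central to
distortion fitting: it maps any metric to an additive one and fixes additive
inputs, either through neighbor joining or through the compatible part of
the split decomposition.
"""

from __future__ import annotations

import warnings
from collections import deque
from typing import Sequence

import dendropy
import numpy as np

from .matrix import DistanceMatrix, check_metric

__all__ = [
    "PhyloTree",
    "tree_to_distances",
    "neighbor_joining",
    "fit_additive_metric",
    "rf_distance",
]


class PhyloTree:
    """An unrooted tree with labeled leaves and nonnegative edge lengths.

    ``adjacency`` maps node id -> {neighbour id: edge length}; ``leaf_labels``
    maps leaf node ids to their taxon labels.  Node ids are arbitrary
    hashables (ints in practice).
    """

    __slots__ = ("adjacency", "leaf_labels")

    def __init__(self, adjacency: dict, leaf_labels: dict):
        self.adjacency = {u: dict(nbrs) for u, nbrs in adjacency.items()}
        self.leaf_labels = dict(leaf_labels)
        labels = list(self.leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if w < 0:
                    raise ValueError(f"negative edge length on ({u},{v}): {w}")
                if self.adjacency.get(v, {}).get(u) != w:
                    raise ValueError("adjacency must be symmetric")
        for u in self.leaf_labels:
            if u not in self.adjacency:
                raise ValueError(f"leaf node {u} missing from adjacency")

    # -- basic accessors ---------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_labels.values()))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def edges(self) -> list[tuple[object, object, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if repr(u) < repr(v) or (repr(u) == repr(v)):
                    out.append((u, v, w))
        # deduplicate symmetric pairs deterministically
        seen = set()
        dedup = []
        for u, v, w in out:
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                dedup.append((u, v, w))
        return dedup

    # -- path metric -------------------------------------------------------
    def distance_matrix(self, labels: Sequence[str] | None = None) -> DistanceMatrix:
        """Path-length distances between all pairs of leaves."""
        if labels is None:
            labels = self.labels
        node_of = {lab: nd for nd, lab in self.leaf_labels.items()}
        n = len(labels)
        out = np.zeros((n, n))
        for i, lab in enumerate(labels):
            dist = self._bfs(node_of[lab])
            for j, lab2 in enumerate(labels):
                out[i, j] = dist[node_of[lab2]]
        out = 0.5 * (out + out.T)  # exact symmetry despite float summation order
        return DistanceMatrix(labels, out)

    def _bfs(self, source) -> dict:
        dist = {source: 0.0}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            du = dist[u]
            for v, w in self.adjacency[u].items():
                if v not in dist:
                    dist[v] = du + w
                    queue.append(v)
        return dist

    # -- splits ------------------------------------------------------------
    def splits(self, include_trivial: bool = False) -> dict[frozenset, float]:
        """Map each split (as the frozenset of leaf labels on the side *not*
        containing the lexicographically smallest label) to the total length
        of the edges inducing it.  Parallel edges created by degree-2 nodes
        contribute to the same split and are summed.
        """
        anchor = min(self.leaf_labels.values())
        out: dict[frozenset, float] = {}
        for u, v, w in self.edges():
            side = self._leaves_beyond(u, v)
            if anchor in side:
                side = frozenset(self.leaf_labels.values()) - side
            if not include_trivial and min(len(side), self.n_leaves - len(side)) < 2:
                continue
            if len(side) == 0 or len(side) == self.n_leaves:
                continue  # edge with all leaves on one side (degree-2 chain end)
            out[side] = out.get(side, 0.0) + w
        return out

    def _leaves_beyond(self, u, v) -> frozenset:
        """Labels of leaves reachable from v without crossing edge (u, v)."""
        seen = {u, v}
        queue = deque([v])
        labels = set()
        while queue:
            x = queue.popleft()
            if x in self.leaf_labels:
                labels.add(self.leaf_labels[x])
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        return frozenset(labels)

    # -- Newick interop (via dendropy) --------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        adjacency: dict[int, dict[int, float]] = {}
        leaf_labels: dict[int, str] = {}
        ids: dict[dendropy.Node, int] = {}

        def nid(node):
            if node not in ids:
                ids[node] = len(ids)
                adjacency[ids[node]] = {}
            return ids[node]

        for node in dt.preorder_node_iter():
            u = nid(node)
            if node.is_leaf():
                leaf_labels[u] = node.taxon.label if node.taxon else str(u)
            for child in node.child_nodes():
                v = nid(child)
                w = child.edge.length if child.edge.length is not None else 0.0
                adjacency[u][v] = float(w)
                adjacency[v][u] = float(w)
        return cls(adjacency, leaf_labels)

    def to_newick(self) -> str:
        # root at an internal node when one exists, else at the first leaf
        internal = [u for u in self.adjacency if u not in self.leaf_labels]
        root = internal[0] if internal else next(iter(self.adjacency))
        ns = dendropy.TaxonNamespace(sorted(self.leaf_labels.values()))
        dt = dendropy.Tree(taxon_namespace=ns)
        dt.is_rooted = False

        def build(u, parent, dnode):
            if u in self.leaf_labels:
                dnode.taxon = ns.get_taxon(self.leaf_labels[u])
            for v, w in sorted(self.adjacency[u].items(), key=lambda kv: repr(kv[0])):
                if v == parent:
                    continue
                child = dnode.new_child(edge_length=w)
                build(v, u, child)

        build(root, None, dt.seed_node)
        return dt.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_leaves={self.n_leaves})"


def tree_to_distances(T: PhyloTree, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Path metric of ``T`` between its leaves (additive by construction)."""
    return T.distance_matrix(labels)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix, check: bool = True) -> PhyloTree:
    """Saitou–Nei agglomeration with deterministic tie-breaking.

    On an additive input the returned tree reproduces ``D`` exactly (up to
    float round-off).  Non-metric inputs (triangle violations) are accepted
    with a warning when ``check`` is true; negative branch-length estimates
    are clamped to zero with the deficit moved to the sibling edge so that
    the two joined branches keep their combined length.
    """
    n = D.n
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if check:
        m1, m3 = check_metric(D)
        if not m3.holds:
            warnings.warn(
                f"input violates the triangle inequality by {m3.worst_violation:g}; "
                "proceeding anyway",
                stacklevel=2,
            )
    labels = D.labels
    leaf_ids = {i: labels[i] for i in range(n)}
    if n == 2:
        w = float(D.values[0, 1])
        return PhyloTree({0: {1: w}, 1: {0: w}}, leaf_ids)

    cap = 2 * n
    M = np.zeros((cap, cap))
    M[:n, :n] = D.values
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    keys: list[str | None] = list(labels) + [None] * (cap - n)
    active = list(range(n))
    nxt = n

    def connect(a, b, w):
        w = max(float(w), 0.0)
        adjacency.setdefault(a, {})[b] = w
        adjacency.setdefault(b, {})[a] = w

    while len(active) > 3:
        idx = np.asarray(active)
        m = len(idx)
        S = M[np.ix_(idx, idx)]
        r = S.sum(axis=1)
        Q = (m - 2) * S - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        ii, jj = min(
            ((i, j) for i, j in cand if i < j),
            key=lambda p: tuple(sorted((keys[idx[p[0]]], keys[idx[p[1]]]))),
        )
        a, b = int(idx[ii]), int(idx[jj])
        dab = S[ii, jj]
        la = 0.5 * dab + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        u = nxt
        nxt += 1
        connect(u, a, la)
        connect(u, b, lb)
        rest = idx[(idx != a) & (idx != b)]
        dnew = np.maximum(0.5 * (M[a, rest] + M[b, rest] - dab), 0.0)
        M[u, rest] = dnew
        M[rest, u] = dnew
        keys[u] = min(keys[a], keys[b])
        active = [x for x in active if x not in (a, b)] + [u]

    a, b, c = active
    dab, dac, dbc = M[a, b], M[a, c], M[b, c]
    center = nxt
    connect(center, a, 0.5 * (dab + dac - dbc))
    connect(center, b, 0.5 * (dab + dbc - dac))
    connect(center, c, 0.5 * (dac + dbc - dab))
    return PhyloTree(adjacency, leaf_ids)


def fit_additive_metric(
    D: DistanceMatrix, method: str = "nj", check: bool = False
) -> DistanceMatrix:
    """Project ``D`` onto an additive metric; additive inputs are fixed points.

    ``method='nj'`` runs neighbor joining and reads path distances off the
    result; ``method='splits'`` sums the pairwise-compatible part of the
    split decomposition.  Both satisfy the two defining properties of an
    additive-fit operator: the output always passes the four-point condition,
    and an additive input is returned unchanged.
    """
    if method == "nj":
        tree = neighbor_joining(D, check=check)
        return tree.distance_matrix(labels=D.labels)
    if method == "splits":
        from .splits import split_decomposition_metric

        return split_decomposition_metric(D)
    raise ValueError(f"unknown method {method!r}; use 'nj' or 'splits'")


def rf_distance(T1: PhyloTree, T2: PhyloTree) -> int:
    """Robinson–Foulds distance: nontrivial splits present in exactly one tree."""
    if set(T1.leaf_labels.values()) != set(T2.leaf_labels.values()):
        raise ValueError("trees must share the same leaf set")
    s1 = set(T1.splits(include_trivial=False))
    s2 = set(T2.splits(include_trivial=False))
    return len(s1 ^ s2)
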