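"""Synthetic data: random trees, distorted distances, and sequence noise.

Everything a distortion-fitting experiment needs is generated here from a
single integer seed:

* random unrooted binary trees (uniform leaf addition or a Yule-style
  bifurcation process) with i.i.d. edge lengths in substitutions per site —
  the default, an Exp(mean 0.05) law on a 100-leaf tree, keeps pairwise
  distances large enough for back-mutations to matter yet below the
  saturation plateau of a four-letter alphabet;
* sequence evolution under the symmetric k-state (Jukes–Cantor type) model,
  site-independent and Markov along edges, giving noisy observed distances
  as mismatch fractions (Hamming) or log-det distances;
* complete datasets ``(tree, source matrix T, observed matrix D)`` where
  ``D`` interpolates between the exact distorted matrix ``f(T)`` and the
  simulated noisy one with mixing weight ``epsilon`` — a reconstruction of
  the usual "theory + measurement noise" blend, isolated here so a different
  noise model can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .matrix import DistanceMatrix
from .transforms import MetricTransform
from .tree import PhyloTree

__all__ = [
    "SimConfig",
    "CharacterMatrix",
    "random_tree",
    "evolve_sequences",
    "hamming_distances",
    "logdet_distances",
    "make_dataset",
    "LogDetSingularError",
]

_ALPHABET = "ACGTEFHIKLMNPQRSWY"  # first k letters are used


class LogDetSingularError(ValueError):
    """A pairwise divergence matrix is singular; the log-det distance is
    undefined (the pair is effectively saturated)."""

    def __init__(self, message: str, pairs: list[tuple[str, str]]):
        super().__init__(message)
        self.pairs = pairs


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``edge_length_law`` is ``(name, params)`` with name in
    {"exponential" (mean), "uniform" (low, high), "gamma" (shape, scale)};
    units are substitutions per site.  ``epsilon`` mixes simulated sequence
    noise into the observed matrix; ``seq_length`` is the alignment length
    used for that simulation.
    """

    n_leaves: int = 100
    topology_model: str = "uniform_addition"
    edge_length_law: tuple[str, dict] = ("exponential", {"mean": 0.05})
    seed: int = 0
    seq_length: int = 1000
    alphabet_size: int = 4
    epsilon: float = 0.0

    def __post_init__(self):
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if self.topology_model not in ("uniform_addition", "yule"):
            raise ValueError(f"unknown topology model {self.topology_model!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.epsilon > 0 and self.seq_length < 1:
            raise ValueError("seq_length must be >= 1 when noise is requested")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")


@dataclass(frozen=True)
class CharacterMatrix:
    """Aligned state sequences over a k-letter alphabet (rows = taxa)."""

    labels: tuple[str, ...]
    states: np.ndarray  # (n_taxa, n_sites) small ints in [0, k)
    alphabet: str

    def __post_init__(self):
        if self.states.ndim != 2 or self.states.shape[0] != len(self.labels):
            raise ValueError("states must be (n_taxa, n_sites)")
        if self.states.size and self.states.max() >= len(self.alphabet):
            raise ValueError("state out of alphabet range")

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def sequence(self, label: str) -> str:
        i = self.labels.index(label)
        return "".join(self.alphabet[s] for s in self.states[i])


def _draw_lengths(rng: np.random.Generator, law: tuple[str, dict], size: int):
    name, params = law
    if name == "exponential":
        return rng.exponential(params["mean"], size)
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], size)
    if name == "gamma":
        return rng.gamma(params["shape"], params["scale"], size)
    raise ValueError(f"unknown edge length law {name!r}")


def random_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Random unrooted binary tree with i.i.d. edge lengths.

    ``uniform_addition`` starts from the 3-leaf star and inserts each new
    leaf on a uniformly chosen edge; ``yule`` repeatedly bifurcates a
    uniformly chosen current leaf.  Topology and lengths are fully determined
    by the seed.  Leaves are labeled ``t01, t02, ...``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_leaves
    width = len(str(n))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]
    adjacency: dict[int, dict[int, float]] = {}
    nxt = [n]  # internal node id counter (leaves are 0..n-1)

    def add_edge(a, b):
        adjacency.setdefault(a, {})[b] = 0.0
        adjacency.setdefault(b, {})[a] = 0.0

    def new_internal():
        u = nxt[0]
        nxt[0] += 1
        return u

    if cfg.topology_model == "uniform_addition":
        center = new_internal()
        for leaf in (0, 1, 2):
            add_edge(center, leaf)
        edges = [(center, 0), (center, 1), (center, 2)]
        for leaf in range(3, n):
            a, b = edges.pop(int(rng.integers(len(edges))))
            del adjacency[a][b]
            del adjacency[b][a]
            mid = new_internal()
            add_edge(a, mid)
            add_edge(mid, b)
            add_edge(mid, leaf)
            edges.extend([(a, mid), (mid, b), (mid, leaf)])
    else:  # yule: bifurcate a random pendant vertex of a rooted tree, then unroot
        root = new_internal()
        tips = [0, 1]
        add_edge(root, 0)
        add_edge(root, 1)
        next_leaf = 2
        while next_leaf < n:
            tip = tips.pop(int(rng.integers(len(tips))))
            # the chosen tip becomes internal, its slot is re-used
            inner = new_internal()
            (parent,) = adjacency[tip].keys()
            del adjacency[tip][parent]
            del adjacency[parent][tip]
            add_edge(parent, inner)
            add_edge(inner, tip)
            add_edge(inner, next_leaf)
            tips.extend([tip, next_leaf])
            next_leaf += 1
        # splice out the degree-2 root
        (a, b) = list(adjacency[root].keys())
        del adjacency[a][root]
        del adjacency[b][root]
        del adjacency[root]
        add_edge(a, b)

    # i.i.d. lengths on the final edge set, in deterministic edge order
    edge_list = sorted(
        {tuple(sorted((u, v))) for u, nbrs in adjacency.items() for v in nbrs}
    )
    lengths = _draw_lengths(rng, cfg.edge_length_law, len(edge_list))
    for (u, v), w in zip(edge_list, lengths):
        adjacency[u][v] = float(w)
        adjacency[v][u] = float(w)

    return PhyloTree(adjacency, {i: labels[i] for i in range(n)})


def evolve_sequences(
    T: PhyloTree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> CharacterMatrix:
    """Evolve an alignment along ``T`` under the symmetric k-state model.

    The root sequence is uniform over the alphabet; along an edge of length
    ``t`` (expected substitutions per site) each site independently keeps its
    state with probability ``1/k + (1 - 1/k) * exp(-k*t/(k-1))`` and
    otherwise switches to one of the other ``k - 1`` states uniformly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.alphabet_size
    L = cfg.seq_length
    nodes = list(T.adjacency)
    root = next((u for u in nodes if u not in T.leaf_labels), nodes[0])
    seqs: dict[object, np.ndarray] = {
        root: rng.integers(0, k, size=L, dtype=np.int64)
    }
    stack = [(root, None)]
    order = sorted  # deterministic traversal order
    while stack:
        u, parent = stack.pop()
        for v in order(T.adjacency[u]):
            if v == parent:
                continue
            t = T.adjacency[u][v]
            p_stay = 1.0 / k + (1.0 - 1.0 / k) * np.exp(-k * t / (k - 1.0))
            parent_seq = seqs[u]
            child = parent_seq.copy()
            mutate = rng.random(L) >= p_stay
            n_mut = int(mutate.sum())
            if n_mut:
                child[mutate] = (
                    parent_seq[mutate] + rng.integers(1, k, size=n_mut)
                ) % k
            seqs[v] = child
            stack.append((v, u))

    leaf_ids = sorted(T.leaf_labels, key=lambda nd: T.leaf_labels[nd])
    labels = tuple(T.leaf_labels[nd] for nd in leaf_ids)
    states = np.stack([seqs[nd] for nd in leaf_ids]).astype(np.uint8)
    return CharacterMatrix(labels, states, _ALPHABET[:k])


def hamming_distances(M: CharacterMatrix) -> DistanceMatrix:
    """Normalised Hamming distances: the fraction of mismatched sites."""
    s = M.states
    n = len(M.labels)
    out = np.zeros((n, n))
    for i in range(n):
        diff = (s[i + 1:] != s[i]).mean(axis=1) if i + 1 < n else []
        out[i, i + 1:] = diff
        out[i + 1:, i] = diff
    return DistanceMatrix(M.labels, out)


def logdet_distances(
    M: CharacterMatrix, on_singular: str = "raise"
) -> DistanceMatrix:
    """Log-det distances ``-ln |det C(x, y)|`` from pairwise divergence
    matrices ``C`` (entry ``(a, b)``: fraction of sites with state ``a`` in
    ``x`` and ``b`` in ``y``).  Additive in expectation under Markov models.

    Singular divergence matrices (saturated pairs) raise
    :class:`LogDetSingularError` listing the pairs; with
    ``on_singular='max'`` they are substituted by the largest finite
    distance instead.
    """
    if on_singular not in ("raise", "max"):
        raise ValueError("on_singular must be 'raise' or 'max'")
    if M.n_sites == 0:
        raise ValueError("log-det distance undefined for zero-length sequences")
    s = M.states.astype(np.intp)
    n = len(M.labels)
    k = len(M.alphabet)
    out = np.zeros((n, n))
    singular: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            C = np.bincount(k * s[i] + s[j], minlength=k * k).reshape(k, k)
            C = C / M.n_sites
            det = np.linalg.det(C)
            if abs(det) < np.finfo(float).tiny:
                singular.append((M.labels[i], M.labels[j]))
                out[i, j] = out[j, i] = np.nan
            else:
                d = -np.log(abs(det))
                out[i, j] = out[j, i] = d
    if singular:
        if on_singular == "raise":
            raise LogDetSingularError(
                f"{len(singular)} saturated pair(s) with singular divergence matrix",
                singular,
            )
        finite = out[np.isfinite(out)]
        out = np.nan_to_num(out, nan=float(finite.max()) if finite.size else 0.0)
    return DistanceMatrix(M.labels, out)


def make_dataset(
    cfg: SimConfig, transform: MetricTransform
) -> tuple[PhyloTree, DistanceMatrix, DistanceMatrix]:
    """Generate ``(tree, T, D)``: a random tree, its path metric ``T``, and
    the observed matrix ``D``.

    With ``epsilon = 0``, ``D`` is exactly the distorted matrix
    ``transform(T)``.  With ``epsilon > 0``, sequences of ``seq_length``
    sites evolve along the tree and ``D`` is the convex mixture
    ``(1 - eps) * transform(T) + eps * Hamming(sequences)``.  Mixture entries
    are deliberately not clamped at the transform's plateau — downstream
    fitting flags saturated grid points instead of silently clipping.
    All randomness flows from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = random_tree(cfg, rng=rng)
    T = tree.distance_matrix()
    D_theory = transform.apply(T)
    if cfg.epsilon > 0:
        seqs = evolve_sequences(tree, cfg, rng=rng)
        D_hat = hamming_distances(seqs).permute(D_theory.labels)
        mixed = (1.0 - cfg.epsilon) * D_theory.values + cfg.epsilon * D_hat.values
        D = DistanceMatrix(D_theory.labels, mixed)
    else:
        D = D_theory
    return tree, T, D
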