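"""Labeled distance matrices and metric-axiom diagnostics.

The central object is :class:`DistanceMatrix`: a labeled, symmetric,
nonnegative square matrix with zero diagonal.  The functions in this module
test the properties that matter for distance-based phylogenetics:

* ``check_metric`` — positivity of off-diagonal entries (M1) and the
  triangle inequality (M3).  Zero diagonal (M0) and symmetry (M2) are
  enforced at construction, so a valid :class:`DistanceMatrix` is always at
  least a pseudometric.
* ``check_four_point`` — the four-point condition characterising additive
  (tree-realisable) metrics: for every quartet the two largest of the three
  pair sums must agree.
* ``check_ultrametric`` — the strong triangle inequality ("all triangles
  isosceles with a short base"), the signature of clock-like trees.
* ``quadruple`` — the split relation on a quartet: which of the three
  pairings has the strictly smallest pair sum.
* ``check_monotone_consistency`` — rank agreement between two matrices
  related by an unknown monotone distortion (weak form anchored at a
  reference taxon, or strong/global form as in non-metric MDS).

Violation magnitudes are absolute differences in the units of the input
distances; tolerances are explicit everywhere (default ``1e-8``) because
published matrices are often rounded to a few decimals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_TOL = 1e-8

__all__ = [
    "DEFAULT_TOL",
    "DistanceMatrix",
    "DistanceMatrixError",
    "AxiomReport",
    "QuadrupleCall",
    "check_metric",
    "check_four_point",
    "check_ultrametric",
    "quadruple",
    "check_monotone_consistency",
]


class DistanceMatrixError(ValueError):
    """Raised when an array cannot be interpreted as a distance matrix."""


class DistanceMatrix:
    """A labeled, symmetric, nonnegative distance matrix.

    Parameters
    ----------
    labels:
        Unique taxon identifiers, one per row/column.
    values:
        Square array of nonnegative reals; entry ``(i, j)`` is the distance
        between taxa ``labels[i]`` and ``labels[j]``.
    tol:
        Absolute tolerance used to validate the zero diagonal, symmetry and
        nonnegativity.  Sub-tolerance defects are repaired (diagonal zeroed,
        matrix symmetrised by averaging, tiny negatives clamped to 0).

    Positivity of off-diagonal entries (M1) is *not* required: representations
    that do not separate taxa yield pseudometrics, which are deliberately
    representable.  Use :func:`check_metric` to test M1/M3.
    """

    __slots__ = ("_labels", "_values", "_index")

    def __init__(self, labels: Sequence[str], values, tol: float = DEFAULT_TOL):
        labels = tuple(str(l) for l in labels)
        if len(set(labels)) != len(labels):
            raise DistanceMatrixError("taxon labels must be unique")
        v = np.array(values, dtype=float)
        n = len(labels)
        if n < 2:
            raise DistanceMatrixError("need at least 2 taxa")
        if v.shape != (n, n):
            raise DistanceMatrixError(
                f"expected a {n}x{n} array for {n} labels, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise DistanceMatrixError("distances must be finite")
        if np.abs(np.diagonal(v)).max() > tol:
            raise DistanceMatrixError("diagonal must be zero (M0)")
        if np.abs(v - v.T).max() > tol:
            raise DistanceMatrixError("matrix must be symmetric (M2)")
        if v.min() < -tol:
            raise DistanceMatrixError("distances must be nonnegative")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        np.clip(v, 0.0, None, out=v)
        v.flags.writeable = False
        self._labels = labels
        self._values = v
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- basic accessors ---------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def values(self) -> np.ndarray:
        """Read-only view of the underlying array."""
        return self._values

    @property
    def n(self) -> int:
        return len(self._labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown taxon label {label!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self._values[self.index(a), self.index(b)])

    def max_offdiag(self) -> float:
        return float(self._values.max()) if self.n >= 2 else 0.0

    def offdiag(self) -> np.ndarray:
        """Condensed vector of the strict upper triangle (unordered pairs)."""
        iu = np.triu_indices(self.n, k=1)
        return self._values[iu]

    # -- transformations ---------------------------------------------------
    def permute(self, order: Sequence[str]) -> "DistanceMatrix":
        """Reorder (or subset) taxa; ``order`` must name existing labels."""
        idx = [self.index(l) for l in order]
        return DistanceMatrix(list(order), self._values[np.ix_(idx, idx)])

    def allclose(self, other: "DistanceMatrix", atol: float = DEFAULT_TOL) -> bool:
        if self._labels != other._labels:
            other = other.permute(self._labels)
        return bool(np.allclose(self._values, other._values, rtol=0.0, atol=atol))

    # -- pandas interop ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._values.copy(), index=list(self._labels), columns=list(self._labels)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tol: float = DEFAULT_TOL) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise DistanceMatrixError("row and column labels must agree")
        return cls(list(df.index), df.to_numpy(dtype=float), tol=tol)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DistanceMatrix(n={self.n}, labels={self._labels[:4]}...)"


@dataclass(frozen=True)
class AxiomReport:
    """Outcome of a single axiom check.

    ``worst_violation`` is an absolute magnitude in distance units and is 0
    exactly when ``holds`` is true at the stated tolerance.  ``witnesses``
    names the taxa achieving the largest violation (empty when none).
    """

    axiom: str
    holds: bool
    worst_violation: float
    witnesses: tuple[str, ...]
    tol: float
    n_violations: int | None = None

    def __post_init__(self):
        if self.holds:
            object.__setattr__(self, "worst_violation", 0.0)
            object.__setattr__(self, "witnesses", ())


_PAIRINGS = ("uv|xy", "ux|vy", "uy|vx")


@dataclass(frozen=True)
class QuadrupleCall:
    """The split relation evaluated on one quartet.

    ``topology`` is one of ``uv|xy``, ``ux|vy``, ``uy|vx`` (relative to the
    argument order ``u, v, x, y``) or ``unresolved`` when the two smallest of
    the three pair sums tie within tolerance.  ``sums`` maps every pairing to
    its pair sum.
    """

    taxa: tuple[str, str, str, str]
    topology: str
    sums: dict[str, float] = field(compare=False)

    def pairs(self) -> tuple[tuple[str, str], tuple[str, str]] | None:
        """The two label pairs of the called topology, or None if unresolved."""
        if self.topology == "unresolved":
            return None
        u, v, x, y = self.taxa
        lookup = {
            "uv|xy": ((u, v), (x, y)),
            "ux|vy": ((u, x), (v, y)),
            "uy|vx": ((u, y), (v, x)),
        }
        return lookup[self.topology]


# ---------------------------------------------------------------------------
# axiom checks
# ---------------------------------------------------------------------------

def check_metric(D: DistanceMatrix, tol: float = DEFAULT_TOL) -> list[AxiomReport]:
    """Test M1 (no zero off-diagonal entries) and M3 (triangle inequality).

    Returns one report per axiom; all ``holds`` true iff ``D`` is a metric
    (M0/M2 being enforced by the type).
    """
    v = D.values
    n = D.n

    # M1: every off-diagonal entry strictly positive (beyond tol).
    iu = np.triu_indices(n, k=1)
    off = v[iu]
    m1_bad = off <= tol
    if m1_bad.any():
        k = int(np.argmin(off))
        wit = (D.labels[iu[0][k]], D.labels[iu[1][k]])
        m1 = AxiomReport("M1", False, float(max(tol - off.min(), np.finfo(float).tiny)),
                         wit, tol, int(m1_bad.sum()))
    else:
        m1 = AxiomReport("M1", True, 0.0, (), tol, 0)

    # M3: d(x,z) <= min_y d(x,y) + d(y,z).  (y = x or z gives slack 0, so the
    # full min over y is safe.)
    through = v[:, :, None] + v[None, :, :]        # [x, y, z] -> d(x,y)+d(y,z)
    best = through.min(axis=1)                     # min over y
    excess = v - best                              # > 0 means violation
    worst = float(excess.max())
    if worst > tol:
        x, z = np.unravel_index(int(np.argmax(excess)), excess.shape)
        y = int(np.argmin(through[x, :, z]))
        m3 = AxiomReport(
            "M3", False, worst, (D.labels[x], D.labels[y], D.labels[z]), tol,
            int((excess > tol).sum()),
        )
    else:
        m3 = AxiomReport("M3", True, 0.0, (), tol, 0)
    return [m1, m3]


def _quartet_index_arrays(n: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), 4)), dtype=np.intp)


def check_four_point(D: DistanceMatrix, tol: float = DEFAULT_TOL) -> AxiomReport:
    """Four-point condition: for each quartet the largest pair sum must not
    exceed the middle one by more than ``tol``.  Additive (tree) metrics pass
    exactly; the worst excess over all quartets is reported otherwise.
    """
    n = D.n
    if n < 4:
        return AxiomReport("MA", True, 0.0, (), tol, 0)
    q = _quartet_index_arrays(n)
    v = D.values
    u, w, x, y = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    sums = np.stack(
        [v[u, w] + v[x, y], v[u, x] + v[w, y], v[u, y] + v[w, x]], axis=1
    )
    sums.sort(axis=1)
    viol = sums[:, 2] - sums[:, 1]
    worst = float(viol.max())
    if worst > tol:
        k = int(np.argmax(viol))
        wit = tuple(D.labels[i] for i in q[k])
        return AxiomReport("MA", False, worst, wit, tol, int((viol > tol).sum()))
    return AxiomReport("MA", True, 0.0, (), tol, 0)


def check_ultrametric(D: DistanceMatrix, tol: float = DEFAULT_TOL) -> AxiomReport:
    """Strong triangle inequality d(x,z) <= max(d(x,y), d(y,z)) over triples."""
    v = D.values
    n = D.n
    if n < 3:
        return AxiomReport("MU", True, 0.0, (), tol, 0)
    # max(d(x,y), d(y,z)) minimised over y.  The trivial choices y = x or
    # y = z reproduce d(x,z) exactly, so they never mask or fake a violation
    # and need no exclusion.
    pairmax = np.maximum(v[:, :, None], v[None, :, :])  # [x, y, z]
    best = pairmax.min(axis=1)
    excess = v - best
    np.fill_diagonal(excess, -np.inf)
    worst = float(excess.max())
    if worst > tol:
        x, z = np.unravel_index(int(np.argmax(excess)), excess.shape)
        y = int(np.argmin(pairmax[x, :, z]))
        return AxiomReport(
            "MU", False, worst, (D.labels[x], D.labels[y], D.labels[z]), tol,
            int((excess > tol).sum()),
        )
    return AxiomReport("MU", True, 0.0, (), tol, 0)


def quadruple(
    D: DistanceMatrix, u: str, v: str, x: str, y: str, tol: float = DEFAULT_TOL
) -> QuadrupleCall:
    """Call the quartet topology of ``(u, v, x, y)`` via the split relation.

    The pairing with the strictly smallest pair sum wins; a tie of the two
    smallest sums within ``tol`` yields ``unresolved``.
    """
    taxa = (u, v, x, y)
    if len(set(taxa)) != 4:
        raise ValueError(f"quartet labels must be distinct, got {taxa}")
    sums = {
        "uv|xy": D.get(u, v) + D.get(x, y),
        "ux|vy": D.get(u, x) + D.get(v, y),
        "uy|vx": D.get(u, y) + D.get(v, x),
    }
    ordered = sorted(sums, key=sums.get)
    if sums[ordered[1]] - sums[ordered[0]] <= tol:
        return QuadrupleCall(taxa, "unresolved", sums)
    return QuadrupleCall(taxa, ordered[0], sums)


def check_monotone_consistency(
    D1: DistanceMatrix, D2: DistanceMatrix, mode: str = "m1"
) -> AxiomReport:
    """Rank consistency between two matrices on the same taxa.

    With ``mode='m0'`` the weak form is tested: for every reference taxon x,
    ``D1(x,y) < D1(x,z)`` must imply ``D2(x,y) < D2(x,z)``.  With
    ``mode='m1'`` the strong (global) form ranges over all pairs of pairs, as
    in non-metric multidimensional scaling.  Ties in ``D1`` impose no
    constraint.  The report counts violating comparisons; the worst violation
    is the largest wrong-way difference in ``D2`` units.
    """
    if set(D1.labels) != set(D2.labels):
        raise ValueError("label sets must be identical")
    if mode not in ("m0", "m1"):
        raise ValueError(f"mode must be 'm0' or 'm1', got {mode!r}")
    B = D2.permute(D1.labels)
    t, d = D1.values, B.values
    n = D1.n
    count = 0
    worst = 0.0
    witness: tuple[str, ...] = ()

    if mode == "m0":
        for xi in range(n):
            ty, dy = t[xi], d[xi]
            lt = ty[:, None] < ty[None, :]
            bad = lt & (dy[:, None] >= dy[None, :])
            idx = np.arange(n)
            bad[xi, :] = False
            bad[:, xi] = False
            if bad.any():
                count += int(bad.sum())
                diff = np.where(bad, dy[:, None] - dy[None, :], -np.inf)
                w = float(diff.max())
                if w >= worst:
                    yi, zi = np.unravel_index(int(np.argmax(diff)), diff.shape)
                    worst = w
                    witness = (D1.labels[xi], D1.labels[yi], D1.labels[zi])
    else:
        iu = np.triu_indices(n, k=1)
        tv, dv = t[iu], d[iu]
        lt = tv[:, None] < tv[None, :]
        bad = lt & (dv[:, None] >= dv[None, :])
        count = int(bad.sum())
        if count:
            diff = np.where(bad, dv[:, None] - dv[None, :], -np.inf)
            p, q = np.unravel_index(int(np.argmax(diff)), diff.shape)
            worst = float(diff.max())
            witness = (
                D1.labels[iu[0][p]], D1.labels[iu[1][p]],
                D1.labels[iu[0][q]], D1.labels[iu[1][q]],
            )
    holds = count == 0
    return AxiomReport(mode, holds, max(worst, np.finfo(float).tiny) if not holds else 0.0,
                       witness, 0.0, count)
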