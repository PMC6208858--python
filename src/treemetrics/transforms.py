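"""Parametric metric-preserving transform families and their inverses.

A *metric-preserving* function maps every metric to a metric when applied
elementwise to its values.  Amenability (zero exactly at zero), subadditivity
and monotonicity are a classical sufficient set of conditions; any concave
amenable function qualifies.  The families implemented here are the ones a
saturating measurement process produces:

``affine``
    ``f(t) = alpha*t + beta`` for ``t > 0`` with ``f(0) = 0`` — the only
    family that preserves *additivity* (tree-realisability), hence the
    discontinuous jump at 0 when ``beta > 0`` is deliberate.
``stretched_exp``
    ``f(t) = a*(1 - exp(-b*t**c))`` — a saturation curve with plateau ``a``,
    rate ``b`` and stretching exponent ``c``.
``jukes_cantor``
    The expected fraction of observably diverged positions after ``t``
    substitutions per site under the symmetric ``k``-state model:
    ``f(t) = (1-1/k)*(1 - exp(-k*t/(k-1)))`` — the stretched exponential with
    ``a = 1-1/k``, ``b = k/(k-1)``, ``c = 1``.
``neg_log``
    Saturation with plateau ``m`` and time scale ``s``,
    ``f(t) = m*(1 - exp(-t/s))``; its inverse is the familiar correction
    ``t = -s*ln(1 - d/m)``.

All families are strictly increasing with closed-form inverses; inverting a
distance at or beyond a family's plateau raises :class:`SaturationError`
(the source distance is unidentifiable there).  User-defined monotone
functions are supported through :class:`CustomTransform`, whose inverse is a
bracketed root search; :func:`check_preserving` can then probe such a
function numerically for amenability, subadditivity, monotonicity and the
sharper necessary-and-sufficient inequality on ``|t - u|``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .matrix import DistanceMatrix

__all__ = [
    "MetricTransform",
    "Affine",
    "StretchedExponential",
    "JukesCantor",
    "NegLogSaturation",
    "CustomTransform",
    "CombinedTransform",
    "SaturationError",
    "PreservationReport",
    "FAMILIES",
    "make_transform",
    "parse_transform_spec",
    "apply_transform",
    "invert_transform",
    "check_preserving",
    "combine_metrics",
]


class SaturationError(ValueError):
    """A distance sits at or beyond a transform's plateau; no preimage exists."""

    def __init__(self, message: str, pairs: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.pairs = pairs or []


class MetricTransform:
    """Base class: a strictly increasing function on [0, inf) with f(0)=0."""

    family: str = "abstract"

    @property
    def params(self) -> dict[str, float]:
        raise NotImplementedError

    @property
    def range_sup(self) -> float:
        """Supremum of the image; distances must stay strictly below it to
        be invertible."""
        return math.inf

    def __call__(self, t):
        raise NotImplementedError

    def inverse(self, d):
        raise NotImplementedError

    # -- matrix-level application -----------------------------------------
    def apply(self, T: DistanceMatrix) -> DistanceMatrix:
        """Elementwise forward transform of the off-diagonal entries."""
        out = np.asarray(self(T.values), dtype=float)
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(T.labels, out)

    def invert_matrix(self, D: DistanceMatrix) -> DistanceMatrix:
        """Elementwise inverse; raises :class:`SaturationError` listing the
        offending taxon pairs if any entry is outside the open range."""
        sup = self.range_sup
        v = D.values
        if v.max() >= sup:
            iu = np.triu_indices(D.n, k=1)
            bad = [
                (D.labels[i], D.labels[j])
                for i, j in zip(*iu)
                if v[i, j] >= sup
            ]
            raise SaturationError(
                f"{len(bad)} distance(s) at or beyond the saturation level "
                f"{sup:g} of {self.family}; source distances unidentifiable",
                bad,
            )
        out = np.asarray(self.inverse(v), dtype=float)
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(D.labels, out)

    def __repr__(self) -> str:
        ps = " ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"{self.family}({ps})"


@dataclass(frozen=True, repr=False)
class Affine(MetricTransform):
    """f(t) = alpha*t + beta for t > 0, f(0) = 0 (discontinuous at 0 when
    beta > 0).  The unique additivity-preserving family."""

    alpha: float
    beta: float = 0.0
    family = "affine"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta < 0:
            raise ValueError("affine requires alpha > 0 and beta >= 0")

    @property
    def params(self):
        return {"alpha": self.alpha, "beta": self.beta}

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where(t > 0, self.alpha * t + self.beta, 0.0)

    def inverse(self, d):
        d = np.asarray(d, dtype=float)
        if np.any((d > 0) & (d < self.beta - 1e-12)):
            raise ValueError(
                f"positive distances below the offset beta={self.beta:g} have no preimage"
            )
        return np.where(d > 0, np.maximum(d - self.beta, 0.0) / self.alpha, 0.0)


@dataclass(frozen=True, repr=False)
class StretchedExponential(MetricTransform):
    """f(t) = a*(1 - exp(-b*t**c)); concave for c <= 1, plateau at a."""

    a: float
    b: float = 1.0
    c: float = 1.0
    family = "stretched_exp"

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ValueError("stretched_exp requires a, b, c > 0")

    @property
    def params(self):
        return {"a": self.a, "b": self.b, "c": self.c}

    @property
    def range_sup(self):
        return self.a

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * -np.expm1(-self.b * np.power(t, self.c))

    def inverse(self, d):
        d = np.asarray(d, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = -np.log1p(-d / self.a) / self.b
            return np.power(w, 1.0 / self.c)


class JukesCantor(StretchedExponential):
    """Observable divergence under the symmetric k-state substitution model.

    ``t`` is in expected substitutions per site; the plateau ``1 - 1/k`` is
    the mismatch fraction of two independent uniform sequences.
    """

    family = "jukes_cantor"

    def __init__(self, k: float = 4):
        if k < 2:
            raise ValueError("alphabet size k must be >= 2")
        self.k = float(k)
        super().__init__(a=1.0 - 1.0 / self.k, b=self.k / (self.k - 1.0), c=1.0)

    @property
    def params(self):
        return {"k": self.k}


@dataclass(frozen=True, repr=False)
class NegLogSaturation(MetricTransform):
    """f(t) = m*(1 - exp(-t/s)); inverse is t = -s*ln(1 - d/m)."""

    s: float
    m: float = 1.0
    family = "neg_log"

    def __post_init__(self):
        if self.s <= 0 or self.m <= 0:
            raise ValueError("neg_log requires s > 0 and m > 0")

    @property
    def params(self):
        return {"s": self.s, "m": self.m}

    @property
    def range_sup(self):
        return self.m

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.m * -np.expm1(-t / self.s)

    def inverse(self, d):
        d = np.asarray(d, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return -self.s * np.log1p(-d / self.m)


class CustomTransform(MetricTransform):
    """Wrap an arbitrary increasing callable; the inverse is numerical.

    Bisection (Brent) on an expanding bracket, tolerance 1e-12.  Useful for
    probing non-preserving functions with :func:`check_preserving`.
    """

    family = "custom"

    def __init__(
        self,
        func: Callable[[float], float],
        name: str = "custom",
        range_sup: float = math.inf,
    ):
        self._func = func
        self._name = name
        self._sup = float(range_sup)

    @property
    def params(self):
        return {}

    @property
    def range_sup(self):
        return self._sup

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.vectorize(self._func, otypes=[float])(t)

    def _inv_scalar(self, d: float) -> float:
        if d <= 0:
            return 0.0
        hi = 1.0
        for _ in range(200):
            if self._func(hi) >= d:
                break
            hi *= 2.0
        else:
            raise SaturationError(f"no preimage found for d={d:g} under {self._name}")
        return brentq(lambda t: self._func(t) - d, 0.0, hi, xtol=1e-12, rtol=8.9e-16)

    def inverse(self, d):
        d = np.asarray(d, dtype=float)
        return np.vectorize(self._inv_scalar, otypes=[float])(d)

    def __repr__(self):
        return f"custom({self._name})"


# ---------------------------------------------------------------------------
# registry / parsing
# ---------------------------------------------------------------------------

FAMILIES: dict[str, Callable[..., MetricTransform]] = {
    "affine": Affine,
    "stretched_exp": StretchedExponential,
    "jukes_cantor": JukesCantor,
    "neg_log": NegLogSaturation,
}


def make_transform(family: str, **params: float) -> MetricTransform:
    try:
        cls = FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown transform family {family!r}; known: {sorted(FAMILIES)}"
        ) from None
    return cls(**params)


def parse_transform_spec(spec: str) -> MetricTransform:
    """Parse ``"stretched_exp a=0.75 b=1.0 c=1.0"`` style specifications."""
    tokens = spec.replace(",", " ").split()
    if not tokens:
        raise ValueError("empty transform specification")
    family, kv = tokens[0], tokens[1:]
    params: dict[str, float] = {}
    for tok in kv:
        if "=" not in tok:
            raise ValueError(f"malformed parameter token {tok!r} in {spec!r}")
        k, v = tok.split("=", 1)
        params[k.strip()] = float(v)
    return make_transform(family, **params)


# Spec-level operation aliases -----------------------------------------------

def apply_transform(z: MetricTransform, T: DistanceMatrix) -> DistanceMatrix:
    return z.apply(T)


def invert_transform(z: MetricTransform, D: DistanceMatrix) -> DistanceMatrix:
    return z.invert_matrix(D)


# ---------------------------------------------------------------------------
# numerical property check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreservationReport:
    """Grid-based verdicts for the metric-preservation properties.

    ``properties`` maps Z1 (amenable), Z2 (subadditive), Z3 (non-decreasing)
    and Zstar (f(|t-u|) <= f(t)+f(u), the necessary-and-sufficient form with
    Z1) to ``(holds, worst_violation, witness)``.  This is a numerical probe
    on a finite grid, not a proof.
    """

    transform: str
    grid_max: float
    grid_n: int
    properties: dict[str, tuple[bool, float, tuple[float, ...]]]

    @property
    def all_hold(self) -> bool:
        return all(h for h, _, _ in self.properties.values())


def check_preserving(
    z: MetricTransform, grid_max: float = 4.0, grid_n: int = 256, tol: float = 1e-10
) -> PreservationReport:
    """Probe Z1/Z2/Z3/Z* for ``z`` on an evenly spaced grid over [0, grid_max]."""
    if grid_max <= 0 or grid_n < 2:
        raise ValueError("need grid_max > 0 and grid_n >= 2")
    t = np.linspace(0.0, grid_max, grid_n)
    f = np.asarray(z(t), dtype=float)
    props: dict[str, tuple[bool, float, tuple[float, ...]]] = {}

    # Z1: f(0) == 0 and f(t) > 0 for t > 0.
    v0 = abs(float(f[0]))
    pos = f[1:]
    z1_holds = v0 <= tol and not (pos <= tol).any()
    if z1_holds:
        props["Z1"] = (True, 0.0, ())
    elif v0 > tol:
        props["Z1"] = (False, v0, (0.0,))
    else:
        k = int(np.argmin(pos))
        props["Z1"] = (False, float(max(tol - pos[k], tol)), (float(t[1 + k]),))

    # Z3: non-decreasing along the grid.
    df = np.diff(f)
    worst = float(np.maximum(0.0, -df).max())
    z3_holds = worst <= tol
    k = int(np.argmin(df))
    props["Z3"] = (z3_holds, 0.0 if z3_holds else worst,
                   () if z3_holds else (float(t[k]), float(t[k + 1])))

    # Z2 and Z*: pairwise over the half grid so t+u stays within [0, grid_max].
    th = t[t <= grid_max / 2]
    fh = np.asarray(z(th), dtype=float)
    fsum = np.asarray(z(th[:, None] + th[None, :]), dtype=float)
    fdiff = np.asarray(z(np.abs(th[:, None] - th[None, :])), dtype=float)
    bound = fh[:, None] + fh[None, :]

    for name, lhs in (("Z2", fsum), ("Zstar", fdiff)):
        excess = lhs - bound
        worst = float(excess.max())
        holds = worst <= tol
        if holds:
            props[name] = (True, 0.0, ())
        else:
            i, j = np.unravel_index(int(np.argmax(excess)), excess.shape)
            props[name] = (False, worst, (float(th[i]), float(th[j])))

    return PreservationReport(repr(z), grid_max, grid_n, props)


# ---------------------------------------------------------------------------
# multi-feature combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinedTransform:
    """Nonnegative linear combination plus discrete-metric components.

    The combined distance is ``sum_i a_i * t_i + sum_i b_i * [t_i > 0]``: the
    most general way of merging per-feature metrics that keeps tree
    compatibility when every feature is tree-compatible.  For each feature at
    least one of ``a_i``, ``b_i`` must be positive.
    """

    weights_linear: tuple[float, ...]
    weights_discrete: tuple[float, ...]

    def __post_init__(self):
        a = tuple(float(x) for x in self.weights_linear)
        b = tuple(float(x) for x in self.weights_discrete)
        object.__setattr__(self, "weights_linear", a)
        object.__setattr__(self, "weights_discrete", b)
        if len(a) != len(b):
            raise ValueError("weight vectors must have equal length")
        if any(x < 0 for x in a + b):
            raise ValueError("weights must be nonnegative")
        for i, (ai, bi) in enumerate(zip(a, b)):
            if ai == 0 and bi == 0:
                raise ValueError(f"feature {i}: both weights are zero")


def combine_metrics(
    matrices: Sequence[DistanceMatrix], ct: CombinedTransform
) -> DistanceMatrix:
    """Combine per-feature distance matrices on identical taxon sets."""
    if not matrices:
        raise ValueError("need at least one matrix")
    if len(matrices) != len(ct.weights_linear):
        raise ValueError("number of matrices must match number of weights")
    ref = matrices[0]
    out = np.zeros_like(ref.values)
    for M, a, b in zip(matrices, ct.weights_linear, ct.weights_discrete):
        if set(M.labels) != set(ref.labels):
            raise ValueError("all matrices must share the same label set")
        v = M.permute(ref.labels).values
        out = out + a * v + b * (v > 0)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(ref.labels, out)
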