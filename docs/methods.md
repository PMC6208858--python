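# Methods

## Problem and model

We consider dissimilarity data `D` on a set of taxa that is assumed to
derive from an additive source metric `T` (path lengths on an unknown
edge-weighted tree) through an unknown elementwise distortion,
`D = f(T)`, where `f` is increasing, subadditive and amenable
(`f(0) = 0`, `f(t) > 0` for `t > 0`). Those conditions are what makes `f`
*metric-preserving*: `f∘t` is again a metric for every metric `t`; any
concave amenable function qualifies. Monotonicity is the weakest usable
link between source and measurement — without at least rank consistency
(`m0`: ranks of distances from a fixed reference are preserved; `m1`:
global rank preservation, as in non-metric MDS) nothing about `T` is
recoverable from `D`.

Two structural facts drive the design:

1. **Only affine maps preserve additivity.** `f(t) = αt + β` for `t > 0`
   (with a jump at 0 when `β > 0`) is the entire additivity-preserving
   class. Any nonlinear distortion generically destroys the four-point
   condition and can flip quartet calls — the package reproduces a concrete
   4-taxon example in which a smooth concave saturation turns `uv|xy` into
   `uy|vx` (the distance analogue of long-branch attraction).
2. **The distortion is inferable.** Let `τ` be an *additive-fit operator*:
   `τ(D)` is always additive, and `τ(D) = D` when `D` is additive. Then
   there exists an additive `T` with `D = f(T)` **iff** the residual
   `R(f) = |D − f(τ(f⁻¹(D)))|` is zero. Minimising `R` over a parametric
   family therefore recovers the distortion and, at the argmin, the
   approximately additive source `f⁻¹(D)`.

For data built from several feature classes, the only combinations of
per-feature metrics that preserve compatibility with a common tree are
nonnegative linear combinations plus discrete-metric components
(`combine_metrics` implements exactly this family; per feature at least one
of the two weights must be positive).

## Additive-fit operators

Two interchangeable `τ` implementations are provided:

* **Neighbor joining** (`method="nj"`, default): standard Saitou–Nei
  agglomeration on the Q criterion, written from scratch so its behaviour
  is fully specified. Ties in Q (within `1e-12` relative) are broken by the
  lexicographically smallest pair of cluster labels (a cluster is labeled
  by its smallest leaf), making results platform-independent. Negative
  branch-length estimates are clamped to zero with the deficit moved to the
  sibling edge, preserving the joined pair's combined length. NJ is
  consistent: on additive input it returns the generating tree exactly
  (topology and lengths), which the suite verifies on 200 random trees with
  4–30 leaves.
* **Split decomposition** (`method="splits"`): brute-force enumeration of
  all `2^(n−1) − 1` bipartitions with their Bandelt–Dress isolation
  indices, then a greedy pass by decreasing index (lexicographic tie-break)
  keeping only splits pairwise compatible with those already kept; the
  output metric is the weighted sum of the kept split pseudometrics.
  Greediness makes the operator deterministic and idempotent; on additive
  input the d-splits are exactly the tree's edge splits with indices equal
  to edge lengths, so the input is reproduced. Weakly compatible
  (network) splits are still *reported* by `all_dsplits`; they are only
  excluded from the projected metric so that it is always tree-realisable.
  Enumeration is capped at 16 taxa — this operator is a desk-scale oracle;
  NJ is the scalable route.

`τ` returns matrices rather than trees because the residual composes it
elementwise with `f`; trees are recovered on demand via `neighbor_joining`.

## The fit

`fit_distortion` evaluates `R` on a full parameter grid, then optionally
polishes the argmin with Nelder–Mead (`xatol = fatol = 1e-6`). A simplex is
used deliberately: `R` is only piecewise smooth, because the fitted tree
topology changes discretely as parameters move. The norm over unordered
pairs is Frobenius by default, with `l1` and `linf` selectable — noise
induces norm-dependent biases, so the choice is exposed rather than fixed.

**Saturation.** For plateaued families (`stretched_exp` plateau `a`,
`neg_log` plateau `m`, `jukes_cantor` plateau `1 − 1/k`), grid points whose
plateau does not exceed the largest observed distance are assigned `R = ∞`
and counted, never clipped; silent clipping would bias the argmin toward
small plateaus. If no grid point is feasible the fit raises.

**Identifiability.** The rate parameter of a saturating family is a pure
time-scale of the hidden axis: `f_{a,b,c}(t) = f_{a,1,c}(b^{1/c} t)`, and a
similarity of the source metric passes through `τ` unchanged, so `R` is
constant in `b` (verified to `1e-9` in the tests). `b` is therefore fixed
at 1 during fitting; `identifiability_note` documents and, given a matrix,
demonstrates the cancellation. The same applies to the `neg_log` time
scale `s` and to the affine slope `α` (with `β = 0`): for `neg_log` the
informative axis is the saturation `m`, and for additive data the affine
residual surface is identically zero — overall scale is unknowable by
design, which is harmless because quartet topology is scale-invariant.

Default grids: `a ∈ [0.40, 1.00]` step 0.025 and `c ∈ [0.40, 1.60]` step
0.05 for `stretched_exp` (the recovery experiments below tighten `c` to
step 0.025 over `[0.6, 1.4]`); `m ∈ [0.76, 2.0]` for `neg_log`;
`k ∈ {2..20}` for `jukes_cantor`.

## Synthetic data and study conditions

`simulate` generates everything the experiments consume, all randomness
flowing from one integer seed through one `numpy` generator.

* **Trees:** unrooted binary, by uniform leaf addition (each new leaf
  subdivides a uniformly chosen edge; default) or a Yule-style process;
  edge lengths i.i.d., default `Exp(mean 0.05)` substitutions/site on a
  100-leaf tree. These defaults were chosen so that back-mutations matter
  but the four-state saturation map of the path metric stays below 0.74 —
  strictly inside the 3/4 plateau — which the suite asserts over 100 seeds
  rather than assumes.
* **Sequences:** site-independent first-order Markov evolution under the
  symmetric k-state model (uniform root, stay probability
  `1/k + (1−1/k)·exp(−kt/(k−1))` along an edge of length `t`). Only the
  symmetric model is implemented: it is the model whose saturation curve
  the default experiments invert, and richer processes would not change
  what the residual machinery is being tested for.
* **Observed distances:** mismatch fractions (Hamming) and log-det
  distances `−ln|det C(x,y)|` over pairwise divergence tables `C`; the
  log-det form is additive in expectation and its four-point violation is
  verified to shrink with sequence length. Singular `C` (saturated pairs)
  is reported per pair, not patched silently.
* **Noise dial:** `make_dataset` returns `(tree, T, D)` with
  `D = (1−ε)·f(T) + ε·Hamming(simulated sequences)`. The convex mixture is
  a reconstruction of the usual "theory + measurement noise" blend and is
  isolated in this one function so an alternative noise model can be
  substituted. Mixture entries are deliberately not clamped at the
  transform's plateau; downstream fitting flags saturated grid points
  instead.

What passing tests on these data do **not** show: real comparative data
have correlated characters, rate heterogeneity, reticulation and
non-monotone measurement error, none of which the generator emulates. The
simulator demonstrates correctness of the inference machinery under its
stated assumptions, not robustness beyond them.

## Numerical choices

* Tolerances are explicit parameters with absolute semantics (default
  `1e-8`); printed matrices rounded to 3 decimals need `~0.05`. Violation
  magnitudes are absolute differences, matching the additive form of the
  conditions being checked.
* Matrix construction eagerly validates squareness, zero diagonal,
  symmetry and nonnegativity (repairing sub-tolerance defects); positivity
  of off-diagonal entries is a *check*, not a requirement, because
  non-injective representations legitimately yield pseudometrics.
* Quartet calls use strict inequality; ties within tolerance are
  `unresolved` rather than broken arbitrarily.
* Transform round-trips are exact to `1e-10` on their open domains;
  inverting at or beyond a plateau raises with the offending taxon pairs.
* `check_preserving` is a numerical grid probe (default 256 points, pair
  conditions on the half grid so `t+u` stays in range), not a proof.

## Experiment scales

The bundled experiments run on one CPU in about a minute: parameter
recovery uses 100-leaf trees over a 25×33 `(a, c)` grid for 10 seeds
(infeasible saturated grid points skip instantly); NJ consistency uses 200
trees up to 30 leaves; the split-decomposition oracle runs at 4–12 taxa;
the round-trip property suite uses 50 random tree/transform pairs at 6–12
leaves plus three ε = 0.1 noisy datasets with 400-site alignments.

## Known limitations

* Split enumeration is exponential and capped at 16 taxa.
* The affine offset `β` is supported in the forward/inverse algebra but not
  fitted by default; with `β > 0` the map is discontinuous at 0 and its
  inverse is only defined for distances ≥ `β`, which real dissimilarity
  data rarely respect.
* Under strong noise the residual's argmin acquires norm-dependent bias;
  the package exposes norms and seeds to study this but implements no
  correction.
* No indels, alignment uncertainty, rate heterogeneity across sites, or
  non-reversible substitution processes; no split-network layout.
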