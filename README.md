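# treemetrics

Distance-based tree building rests on *additive* metrics: distances that are
path lengths between the leaves of an edge-weighted tree, characterised by
the four-point condition

    d(u,v) + d(x,y)  <=  max{ d(u,x) + d(v,y),  d(u,y) + d(v,x) }     for all quartets.

Measured dissimilarities are rarely additive, and often the deviation is
*systematic*: what is observed is `D = f(T)` for an additive source metric
`T` and an unknown increasing, subadditive distortion `f` — saturation of
sequence divergence (the Jukes–Cantor curve) being the canonical example.
Such a distortion keeps `D` a metric but can silently flip quartet calls,
the distance analogue of long-branch attraction, so trees built directly
from `D` can be wrong.

The key observation this package operationalises: the distortion itself is
inferable from the data alone. Let `fit_additive` be any operator that maps
a metric to an additive one and fixes additive inputs (neighbor joining, or
the compatible part of the Bandelt–Dress split decomposition). Then the
non-additivity residual

    R(f)  =  | D − f( fit_additive( f⁻¹(D) ) ) |

(under a matrix norm over unordered pairs) vanishes exactly when `f⁻¹(D)` is
additive. Scanning a parametric family — e.g. the stretched exponential
`f(t) = a·(1 − exp(−b·tᶜ))` — for the minimum of `R` recovers the distortion
up to a time-scale (the rate `b` rescales the hidden axis and cancels in the
round trip, so it is unidentifiable and held fixed) and yields an
approximately additive source matrix `f⁻¹(D)` ready for tree building. This
makes distance-based phylogenetics well-posed even without a mechanistic
model of the process — relevant wherever evolution-like descent is studied
without a substitution model: languages, manuscript traditions, cultural
artefacts, alignment-free genomics.

The toolkit, for users of distance-based phylogenetics and comparative
"cultural evolution" data alike:

* `treemetrics.matrix` — labeled distance matrices; checks for the metric
  axioms, the four-point condition, ultrametricity, quartet (split-relation)
  calls, and rank consistency between matrices (`m0`/`m1`).
* `treemetrics.transforms` — monotone transform families with closed-form
  inverses (`affine`, `stretched_exp`, `jukes_cantor`, `neg_log`, custom),
  numerical metric-preservation probes, multi-feature combination.
* `treemetrics.splits` — Bandelt–Dress isolation indices, d-split
  enumeration, split-decomposition projection to a tree metric.
* `treemetrics.tree` — from-scratch, deterministic neighbor joining;
  tree ↔ matrix conversion; Robinson–Foulds distance; Newick IO.
* `treemetrics.fit` — the residual `R(f)` and grid/simplex minimisation
  over a family (`fit_distortion`).
* `treemetrics.simulate` — seeded random trees, symmetric k-state sequence
  evolution, Hamming and log-det distances, complete noisy datasets.

## Worked example

A 4-taxon metric (taxa `u, v, x, y`, bundled as `worked_example()`) whose
raw quartet signal is wrong:

```python
import numpy as np
import treemetrics as tm
from treemetrics.fit import fit_distortion

D = tm.worked_example()
print(tm.quadruple(D, "u", "v", "x", "y").topology)
# uy|vx        <- the smallest pair sum pairs u with y: the wrong tree

for r in tm.all_dsplits(D):
    if not r.is_trivial:
        print(r.side_a, r.side_b, round(r.alpha, 3))
# ('u', 'y') ('v', 'x') 0.066    <- split decomposition agrees with the
# ('u', 'v') ('x', 'y') 0.045       wrong quartet (isolation indices)

res = fit_distortion(D, "neg_log", {"m": np.linspace(0.76, 2.0, 63)})
print(res.summary())
# argmin:    {'m': 1.0}  residual=0.00038378
```

The fit identifies the saturation plateau `m = 1.0`, i.e. the distortion
`d = 1 − exp(−t/10)` (the time scale 10 is the unidentifiable rate; any
choice gives the same residual). Undoing it repairs the phylogenetic
signal:

```python
T = res.recovered                      # = f^-1(D), the pulled-back matrix
print(tm.check_four_point(T, tol=0.05).holds)   # True  (additive up to rounding)
print(tm.quadruple(T, "u", "v", "x", "y").topology)  # uv|xy  <- flipped, correct
print(tm.neighbor_joining(T).to_newick())
# (u:5.997,v:0.995,(x:1.012,y:6.996):0.995);   (lengths abridged)
```

The residual at the argmin (3.8e-4) is pure print-rounding noise: the
matrix ships with three decimals.

At scale, the same machinery recovers a distortion's parameters from a
100-leaf tree whose distances were saturated by the four-letter
substitution curve (`a = 3/4`, `c = 1`): `fit_distortion` on such data
locates the plateau and stretching exponent on a 0.025-step grid exactly,
and degrades gracefully as sequence-sampling noise is mixed in
(`SimConfig(epsilon=...)`).

## Command line

```sh
treemetrics check    --matrix D.phy
treemetrics fit      --matrix D.phy --family stretched_exp \
                     --grid a=0.4:1.0:25 --grid c=0.6:1.4:33 --tau nj
treemetrics tree     --matrix D.phy --out tree.nwk
treemetrics splits   --matrix D.phy --out splits.nex
treemetrics simulate --n 100 --transform "jukes_cantor k=4" --seed 1 \
                     --out-dir dataset/
```

Matrices are PHYLIP square format or labeled CSV; trees are Newick; splits
are NEXUS splits blocks; fitted grids are CSV.

## Documentation

`docs/methods.md` describes the model and procedure, the simulator's study
conditions, numerical choices and known limitations.
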