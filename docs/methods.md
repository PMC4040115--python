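# Methods

This note documents the models, algorithms, numerical choices and limitations
behind `scanedge`. Symbols: a region has `n` SUs with at-risk populations
`pop_i`; a dataset has observed counts `N_i` with expectations
`μ_i = λ·pop_i`; region-wide totals are written `total_cases` and
`total_population` (the scan literature's `n` and `N`, renamed to avoid the
clash with `n` = number of SUs).

## Null model

Under risk homogeneity every SU shares the global incidence λ, and counts are
independent Poisson: `N_i ~ Pois(λ·pop_i)`. Populations are real-valued
(mean annual live births), never rounded. The two incidences used as
defaults throughout — 2.26% (all birth defects) and 0.48% (cardiovascular
birth defects) — are realistic registry-derived annual rates for this kind of
surveillance problem.

Reproducibility contract: dataset `k` of a run with master seed `s` is drawn
from the child stream `SeedSequence(entropy=s, spawn_key=(k,))`, so any
subset of datasets can be regenerated independently and a parallel execution
is bit-identical to a serial one. Scan replicates for dataset `k` use
`spawn_key=(1, k)` and the permutation test `spawn_key=(2,)`, keeping all
streams disjoint.

## The circular scan

Zones are circles centred on each SU centroid; the SUs are ranked by centroid
distance from the centre and included cumulatively while the zone population
stays within `max_pop_fraction` (default 50%) of the total. Centroids at
exactly equal distance enter together — a circle covers both or neither — and
duplicate member sets reached from different centres are kept once.

For a zone `z` with `n_z` cases and population `N_z`, the statistic is the
Poisson log-likelihood ratio

    LLR(z) = n_z log(n_z / (λ N_z)) + (n − n_z) log((n − n_z) / (λ (N − N_z)))

if `n_z` exceeds its null expectation, else 0, with `x log x → 0` at zero
counts. Computation is entirely in log space (the product form overflows for
realistic counts) and vectorised: zone membership is a dense 0/1 matrix, so
scoring all Monte-Carlo replicates of a dataset is one matrix product.

**Inference is conditional by default.** Replicates redistribute the observed
total multinomially with probabilities proportional to expected counts, and
λ in the LLR is the count vector's own `total_cases/total_population`
(`lambda_mode="estimated"`). With an estimated λ the statistic is a
nonnegative KL-type quantity, zero only at a perfectly proportional count
vector — the form the widely used R implementations compute. The package
also exposes `lambda_mode="nominal"` (the stated incidence) and
`replicates="poisson"` (unconditional). These options are *not* neutral:
the proportional form of the LLR with a nominal λ drops a factor that depends
on the total, so whole-region deficits (`total_cases < λN`, which happens in
a third of null datasets at these incidences) drive every zone's value to the
zero floor, tie the observed maximum with all replicates, and make the
Monte-Carlo test noticeably conservative (measured rejection ≈ 3.9% instead
of 5% at the higher incidence). The conditional default restores nominal
behaviour; the nominal mode remains available for studying exactly this
phenomenon.

The p-value is the rank rule `p = (1 + #{replicate max ≥ observed max}) /
(n_mc + 1)`; ties count toward the numerator. Ties for the maximal LLR break
to the earliest enumerated zone (lowest centre index, then fewest members) —
a deterministic convention, documented rather than standard.

## Participation rates

Each significant most likely cluster under the null is a wrongly detected
cluster. Each WDC carries `1/m` of the overall type I error, shared equally
among its `l_j` member SUs: `P_i = Σ_j I_ij/(m·l_j)`, hence `P_i ≥ 0`,
`Σ P_i = 1`, expected value `1/n` per SU. With `m = 0` the vector is
undefined and the code raises instead of returning zeros. The overall rate
`m/n_datasets` is reported with a Wilson score 95% interval (a standard
binomial interval choice; nothing downstream depends on it).

## Edge geometry

`ε_i = 1 − 2 d_i / D` with `d_i` the minimal Euclidean distance from SU *i*'s
centroid to the region boundary (interior rings count as boundary) and `D`
the region depth — the maximal distance from any interior point to the
boundary. The deepest point lies on the medial axis and `D` equals the
maximal inscribed-circle radius, so no explicit skeleton construction is
needed: `D` is the maximum of the distance-to-boundary field, evaluated on a
regular grid (default spacing: bounding-box diagonal / 2000) and refined by
Nelder–Mead from the best grid point. The 1-Lipschitz property of the
distance field guarantees the grid stage alone is within one spacing of the
truth; tests cross-check against a Chebyshev-centre linear program on convex
polygons, a fine-grid brute force on an L-shaped polygon, and shapely's
maximal-inscribed-circle routine as independent oracles. Centroid distances
are clipped at `D` so ε never leaves `[−1, 1]` (a centroid can sit marginally
deeper than the numerically estimated depth). In multi-part regions each
component gets its own `D`, so ε reaches −1 inside every component.
Coordinates must be planar; lon/lat inputs are rejected at the I/O layer
because every quantity above is a Euclidean distance.

## The E test

`E = Σ_i ε_i (P_i − n⁻¹)`. Under spatial homogeneity of type I error the
`P_i` are exchangeable across SUs, `E` has expectation 0, and its null
distribution is obtained by permutation: redistribute the observed `P_i`
uniformly at random among the SUs `B` times (default `B = 99 999`) and
recompute `E`. The observed statistic is included in the ranking collection,
so the smallest attainable p-value is `1/(B+1) = 10⁻⁵` at the default `B`.
Comparisons carry an absolute tolerance of `1e−12` so exact permutation ties
(e.g. constant ε) are counted as ties despite floating-point summation order.

Sidedness: the alternative is `E ≠ 0`, so the default p-value is two-sided on
`|E|`; one-sided `upper` and `lower` rules are exposed for users who specify
the gradient direction in advance. A positive `E` indicates an ascending
centre-to-edge gradient of participation, a negative `E` a descending one
(WDCs preferentially central).

A caveat inherent to the test (not specific to this implementation): the
permutation null treats the `P_i` as exchangeable, but participation rates
estimated from a *finite* set of WDCs are spatially correlated (a WDC is a
contiguous set of SUs). The test is therefore best read as a test of spatial
homogeneity of type I error via its edge profile, and confounders such as a
centrally concentrated population should be checked separately — the package
reports the Spearman correlation between `P_i` and population for exactly
this purpose.

## Synthetic regions

The generator produces three geometries: `square_grid` (unit cells),
`perturbed_grid` (jittered quasi-regular points inside an irregular polygon
built from low-order radial harmonics — irregular but without thin necks, so
the region is deep enough for a clear ε gradient), and `convex_blob`.
Populations are uniform, log-normal, or log-normal tilted toward the centre.
The log-normal default (median 35, σ = 0.9) targets quartile cut-offs near
17/35/70 births per SU, the pattern of ZIP-code-sized tracts in a rural
European region; `make_auvergne_like` combines 221 such SUs with a mild
central population gradient (strength 0.6), emulating the tessellation
structure of the region that motivated the problem without bundling any real
census geography (none is publicly deposited, and the methods are
geometry-generic). Total population is left free — it is not a published
quantity — and scales only the case counts, not the geometry.

What passing tests on these regions shows: calibration, exactness and
oracle-equivalence of the statistics on geometries with realistic depth and
population skew. What it does not show: magnitudes tied to a particular real
geography (e.g. a specific observed `E` value), which depend on the true
boundary shape and tract layout.

## Problem sizes and numerical defaults

The package's own reference experiment (`scripts/acceptance.py` and the
statistical tests) uses a 100-SU region, 1 000 null datasets per incidence
and 199 scan replicates — sizes chosen so the full pipeline runs in minutes
on a single core while leaving the binomial envelope around the 5% level
tight enough to detect miscalibration. The E-test calibration check uses 500
runs at `B = 999`; exactness checks enumerate all permutations at `n = 3`.
Grid resolutions in tests are coarsened (0.005–0.02) where the default would
be needlessly fine for the shapes involved.

## Known limitations

- Circular zones only; no elliptic or flexibly shaped windows, no space-time
  scan, no secondary-cluster reporting (the most likely cluster is the unit
  of analysis throughout).
- The medial depth is numerical, not algebraic; pathological polygons with
  features finer than the grid resolution need an explicitly smaller
  `resolution`.
- ε is a pure distance-to-edge measure: two SUs at equal distance are treated
  alike even if one sits in a narrow peninsula and is more isolated;
  accounting for such configurations would require a different geometric
  functional.
- The expected participation rate is the constant `n⁻¹`; replacing it with a
  covariate-adjusted vector (summing to 1) is a straightforward extension not
  implemented here.
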