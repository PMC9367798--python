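# Methods

This note documents the models implemented in `lesim`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and known limitations.

## Grid model

All stages operate on co-registered rectangular grids with square cells.
Coordinates are 0-based `(row, col)` with row 0 at the top; `origin` is
the map coordinate of the lower-left corner, as in the ESRI ASCII grid
header. The default cell is 30 m (900 m²); areas are reported in km² as
`cells × cell_size² / 10⁶`. nodata cells are excluded from every
statistic, transition count, and allocation. Distances are
center-to-center planar Euclidean in map units (an exact distance
transform); no geodesic correction is applied, which is adequate at
city-region scale. Raster I/O covers ESRI ASCII grids and TIFF; TIFF
georeferencing is carried in a small JSON sidecar (cell size, origin,
nodata) rather than embedded tags. Reprojection is out of scope; when a
coarse layer (e.g. a 1 km population raster) must be brought to the
common resolution, nearest-neighbor resampling is the supported rule.

## Land ecological security index

**Standardization.** Indicator `j` in unit `i` becomes
`H_ij = (x_ij − min_j)/(max_j − min_j)` for positive (more-is-safer)
indicators and `H_ij = (max_j − x_ij)/(max_j − min_j)` for negative ones.
A constant column is rejected: it carries no information and its scaling
is undefined.

**Entropy weights.** `p_ij = H_ij / Σ_i H_ij`,
`e_j = −(1/ln m) Σ_i p_ij ln p_ij` (with `0·ln 0 := 0`), and
`w_j = (1 − e_j)/Σ_k (1 − e_k)`. A column summing to zero is shifted by
10⁻⁴ before proportioning; a column constant across units receives weight
0. Weights are used only to *rank* siblings in the hierarchy — the
catastrophe-progression aggregation itself is weight-free, which is the
method's point: importance enters through rank order, not multipliers.

**Catastrophe-progression aggregation.** The hierarchy (by default the
standard PSR tree: 3 criteria, 9 factors, 19 indicators, shipped with
published entropy weights as the ranking fixture) is folded bottom-up.
A node with `k` children uses the catastrophe model of arity `k` (fold,
cusp, swallowtail, butterfly for 1–4); nodes with more than four children
are rejected rather than split, since no standard model exists beyond
arity 4. The child at rank position `k` is normalized as `v^(1/(k+1))`
(exponents ½, ⅓, ¼, ⅕ for control variables a–d) and siblings combine by
mean under the complementary principle (the default everywhere, matching
the assumption that sibling controls are correlated) or by minimum under
the non-complementary principle (a per-node option). The importance of an
internal node is the sum of its descendant leaf weights; ties keep
declaration order. Aggregation is strictly monotone in every leaf, maps
all-0 to 0 and all-1 to 1, and the complementary result always dominates
the non-complementary one (mean ≥ min).

**Index adjustment.** Raw scores crowd near 1, so reference levels
`n_0 … n_10` are computed by aggregating the ranked hierarchy with every
leaf at `i/10`; strict monotonicity of the folding guarantees the levels
strictly increase from 0 to 1. A raw score `L ∈ [n_i, n_{i+1}]` becomes
`(L − n_i)/(n_{i+1} − n_i) × 0.1`. Taken literally, that formula collapses
every decile onto `[0, 0.1]` and destroys global ordering, which makes a
subsequent one-dimensional classification ill-defined; the default
**monotone** variant therefore adds the decile offset `i × 0.1`, giving a
piecewise-linear, order-preserving index on `[0, 1]`. The offset-free
**verbatim** variant is retained behind a flag for comparison. An exact
hit on a level starts its own interval (`L = n_i` maps to fraction 0),
except the top level `n_10 = 1`, which closes the last interval at 0.1 —
with the offset, both conventions give identical values everywhere.

## Zoning

Fisher–Jenks natural breaks on the adjusted index, computed by exact
dynamic programming over the sorted values (O(k·n²) with prefix sums) —
deterministic, never the heuristic iterative variant. Four classes map to
UDZ < EOZ < EBZ < ECZ in ascending security. Boundary convention: the
three lower classes are closed on their upper break (`b_{k−1} < v ≤ b_k`)
and the core zone is strictly open below (`v > b_3`); values below the
observed minimum clamp to UDZ. Because classification runs on the
adjusted index while security levels are conventionally reported in raw
units, the per-zone raw threshold is reported as the minimum raw score
observed in the class, alongside per-zone area, share, and mean raw
score.

## Driver weighting

For each land class, presence/absence cells are sampled without
replacement, `⌊fraction × n⌋` per stratum (default fraction 0.05), from
the period-end map, under a mandatory seed recorded in the result.
Collinearity is screened by VIF (`1/(1 − R²)` from regressing each factor
on the others; TOL = 1/VIF; flag at VIF ≥ 10). The logit model is fit by
maximum likelihood on z-scored factors — standardization makes
coefficient magnitudes comparable across measurement units (meters vs
persons), which the weighting requires — with Newton iterations
(tolerance 10⁻⁸, cap 100). On perfect separation or non-convergence the
model is refit with a small ridge penalty (α = 10⁻⁶) and flagged; the
separating factor is treated as significant. Factors with Wald
`p ≥ 0.05` (configurable) are dropped; survivors receive weight
`|coef| / Σ|coef|` with the coefficient sign carried separately. The
weights are scale-invariant and sum to 1 per class. An a-priori
include-list lets a class exclude factors before fitting. For very rare
classes no factor may reach significance at α = 0.05; the acceptance
pipeline then relaxes α to 1 for that class, keeping all factors weighted
by coefficient magnitude.

## Suitability atlases

Per class: a Boolean restriction mask times a weighted linear combination
of fuzzy factors. Restrictions exclude cells already of the class (a cell
cannot "convert to" its own class), protected categories, and — for
construction under EP — the ecological core zone. Protected categories
(permanent basic farmland, water, urban land at the base date) are
additionally *frozen* in the automaton: they never change class in either
direction. This reading — protection as exclusion-from-change rather than
exclusion-from-receiving — is the only one under which farmland can keep
existing on basic-farmland cells. Memberships are linear min–max
(rising for `+` factors, falling for `−`), consistent with the
standardization used elsewhere; sigmoidal families were deliberately not
adopted. Suitability is kept as float in [0, 1] (no byte quantization);
restricted cells are exactly 0, and on unrestricted cells the result is a
convex combination of the memberships.

## CA–Markov

**Markov stage.** `P[u][v]` is the fraction of class-u cells at the base
date observed as v at the later date, over cells valid in both maps;
absent classes carry identity rows. Demands are integerized by
largest-remainder rounding applied per matrix row (each class's outflow
sums exactly to its base count); per-class targets are the column sums,
so the total cell count is conserved exactly and targets agree
cell-for-cell with the per-pair demands the allocator satisfies.

**CA stage.** Default 10 cycles with a 5×5 contiguity window
(edge-truncated, no wraparound — map edges are study-area boundaries).
Per-pair demand follows a linear schedule: the cumulative target at cycle
`t` is `t/T` of the pair total, largest-remainder rounded, distributing
change evenly over cycles. Within a cycle, gaining classes are processed
in descending remaining demand (ties by class code), sources within a
gaining class likewise; candidate cells of the source class are scored
`Q_v × (0.01 + h_v)` with the neighborhood fraction `h_v` computed from
the cycle-start state, and the top-scoring cells convert, ties broken by
(row, col). The ε = 0.01 floor keeps isolated high-suitability cells
reachable when they have no same-class neighbors; the multiplicative
(rather than gating) role of the contiguity filter is a design choice of
this implementation. A cell changes at most once per cycle; frozen cells
and zero-suitability (restricted) cells never change. If a pair's
eligible cells run out, the shortfall is logged and the remainder carried
forward. The allocator uses no randomness, so identical inputs produce a
bit-identical map; the config seed is recorded in the run log for
provenance of upstream sampling.

## Validation

Kappa is computed over the full non-nodata census, not a sample:
`p0 = trace/total`, `pe = Σ row_c·col_c / total²`,
`kappa = (p0 − pe)/(1 − pe)`. Change tables report per-class area at two
dates, the difference in km², and the percentage of the base area; the
differences across classes sum to zero by construction. Zone-by-class
tables report each class's area per ecological zone with row proportions
summing to 100%. Published tables can be passed directly as areas — the
accounting operations accept either maps or area mappings.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* **Landscape (t0):** budget-constrained nearest-nucleus growth — random
  nuclei per class (count set by the mean patch radius, default 8 cells),
  cells assigned in order of distance to their nearest nucleus, passing
  to the next-nearest class once a class's budget fills. Produces
  contiguous patches meeting the class budget exactly. The default budget
  (farmland 0.28, woodland 0.40, grassland 0.02, water 0.08, construction
  0.21, unused 0.01) reflects a peri-urban mix dominated by farmland,
  woodland and construction.
* **Change (t1):** for each declared pair intensity `p(u→v)` (default:
  construction expanding into farmland 0.08 and woodland 0.03 per decade,
  plus minor reshuffling), exactly `round(p × n_u)` cells flip, chosen by
  descending adjacency to the gaining class — spatially autocorrelated,
  boundary-biased change whose transition matrix recovers the declared
  intensities up to integer rounding.
* **Drivers:** meandering river and highway lines, towns placed on
  construction cells, scattered rural settlements; distance surfaces by
  exact distance transform; population decaying exponentially with
  distance to town under multiplicative lognormal noise (sd 0.15);
  elevation as a smoothed Gaussian field scaled to 0–500 m with slope as
  its gradient magnitude.
* **Indicators:** normal draws per indicator over square blocks of the
  grid (default 10×10 cells per unit); in coupled mode the land-cover
  share indicators (construction, woodland, water) are replaced by the
  actual block shares so maps and tables agree.

All randomness flows from one spec seed through named substreams
(landscape / drivers / indicators), so regenerating one component never
perturbs the others.

What the generator does **not** emulate: real terrain morphology (valley
networks, aspect), heteroskedastic or spatially correlated indicator
noise, measurement error in class maps, multi-scale settlement structure,
and any calibration to a particular city's statistics. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms — conservation, determinism, constraint satisfaction,
parameter recovery — not predictive skill on real landscapes.

## Problem sizes and defaults

Simulation-scale tests and the acceptance pipeline run on a 200×200
(40,000-cell) world with 10 CA cycles and a 5×5 filter — large enough for
stable transition estimates (recovery within ±0.02) and meaningful
neighborhood effects, small enough to iterate quickly. Statistical
recovery uses n = 5,000 logit samples (slope recovered within ±0.1).
Oracle-equivalence checks run exhaustive enumeration at the sizes where
it is exact: all ordered partitions for Jenks at n ≤ 15, brute-force
greedy allocation on grids up to 8×8 across 100 seeds, all-pairs minima
for the distance transform on 5×5 grids.

## Known limitations

* The allocator is a deterministic greedy stand-in for proprietary
  multi-objective land allocation; it reproduces the documented behavior
  (suitability-driven growth adjacent to existing patches) but not any
  particular vendor's tie-breaking or conflict resolution.
* Cycles are exposed independently of the projection horizon; the default
  of 10 matches a one-cycle-per-year reading of a 10-year step.
* Logistic fits ignore spatial autocorrelation among sampled cells;
  p-values are anti-conservative on strongly clustered landscapes.
* Whether presence is sampled from the base- or end-year map is a free
  choice; this implementation samples from the period-end map (presence
  at period end) and records it in the result.
* No reprojection: all inputs must already share a grid.
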