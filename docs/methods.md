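# Methods

## Data model

A study region is a lattice of `n` units — either a regular raster of
square cells (row-major, 0-based; the centroid of cell (r, c) is
((c + 0.5)s, (r + 0.5)s) for cell size s) or a collection of polygons —
carrying one non-negative count per unit.  Spatial relations are binary
weights: rook (shared edge / shared boundary of positive length), queen
(additionally shared corners / any touch) or a centroid-distance
threshold.  Queen contiguity is the default everywhere, and all weights
are symmetric 0/1 matrices; G\* carries the self weight (w_ii = 1),
local Moran's I does not — the standard conventions for each statistic.

Patch perimeters on rasters count exposed cell edges (interior holes
contribute); on polygon lattices they are the boundary length of the
polygon union.  Patches are delimited with rook connectivity, so a
diagonal-only touch does not fuse two patches; because rook components
share no edges, summing per-patch perimeters equals the perimeter of
the whole mask.

## Detectors

**Poisson circular scan.**  Windows are centred on every unit; for each
centre the distinct centroid distances generate a nested family of
member sets, truncated when the window's share of the background
population exceeds `max_fraction` (default 0.5).  The simulated grids
carry no population layer, so each cell has population 1 and the
expected count is μ = C·(window cells)/n (uniform risk); a per-unit
population vector switches to the population-weighted μ.  Windows are
scored in log space with the one-sided Poisson likelihood ratio
(LR = 1 for c ≤ μ: a deficit is not a hotspot).  Significance is by
Monte Carlo: the cell values are randomly relabeled across units
`n_sim` times, the maximum log-LR recorded each time, and
p = (1 + r)/(1 + n_sim) from the rank of an observed window's log-LR in
that max-LR null — which accounts for the multiplicity of windows.
Secondary clusters are reported greedily in descending LR, skipping
windows that overlap an already-reported cluster; ties prefer the
smaller window, then the lower centre id, making results deterministic.
The enumeration-by-distinct-radii is exhaustive: a continuous-radius
scan visits exactly the same member sets.

**Getis–Ord G\* and local Moran's I.**  Per-unit statistics as defined
above, with S² the population (divide-by-n) variance.  The default
inference is the analytic one-sided upper z-test under the
randomization hypothesis; the moment formulas (for binary weights)

* G\*: E = W_i/n, Var = W_i(n−W_i)σ²/((n−1)n²x̄²)
* Moran: E = −W_i/(n−1),
  Var = W_i(n−b₂)/(n−1) + (W_i²−W_i)(2b₂−n)/((n−1)(n−2)) − W_i²/(n−1)²,
  with b₂ the fourth standardized moment of x

are verified in the test suite against exhaustive enumeration of all
value-to-unit assignments at small n.  A Monte Carlo permutation mode
is available; on strong signals (z > 4) it flags the same units.
Hotspot extraction keeps, for G\*, units with p ≤ α and z > 0; for
Moran additionally the statistic and the unit's own deviation from the
mean must be positive (high–high clusters only — low–low clusters are
significant positive-I configurations but not hotspots).  An optional
Benjamini–Hochberg step-up correction is applied before thresholding;
the default is the uncorrected per-unit test at α = 0.05.  Constant
fields have undefined z and are flagged per-unit rather than raising.

**AMOEBA.**  From every seed, the ecotope starts as the seed alone and
repeatedly considers the first-order (queen) neighbours of the current
ecotope.  The statistic optimized is the standardized G\* of the member
set S treated as the seed's neighbourhood,

    z(S) = (Σ_S x − |S|·x̄) / sqrt(|S|(n−|S|)σ²/(n−1)).

The source descriptions speak of maximizing "G\*"; raw G\* is a mass
share that never decreases when any non-negative-valued cell is added,
so a size-penalized form is required for growth to terminate, and the
z-score is the form the region-growing literature uses.  At fixed
|S| the z is monotone in the added mass, so the optimal frontier subset
of each cardinality is a prefix of the value-sorted frontier; scanning
prefixes therefore evaluates every frontier combination exactly (the
test suite checks this against brute-force subset enumeration, and
against global connected-subset search in the planted-contrast regime).
Frontier units rejected in a round are excluded from all later rounds;
growth stops when no prefix improves z.  Note the greedy rounds do not
generally attain the global optimum over all connected supersets on
noise fields — optima requiring non-improving intermediate cells are
unreachable by construction; this is a property of the algorithm, not
of the implementation.

Each seed's ecotope is tested by regrowing from the same seed position
on relabeled fields and ranking the observed z among the null z's.
Significant (p ≤ α, z > 0) ecotopes are resolved greedily by descending
z, discarding overlapping competitors; the survivors' union is the
hotspot labeling.  The growth kernel is JIT-compiled (numba), since a
benchmark replicate regrows every seed on every permuted field.

Two caveats, measured on the synthetic scenarios and worth knowing
before trusting AMOEBA output: (1) the per-seed regrowth null controls
the per-test level but not the flagged-*area* fraction — under pure
noise the accepted maximum-z ecotopes are exactly the largest noise
clumps, so the flagged area at α = 0.05 averages ~0.12 of the grid
rather than ≤ 0.05; (2) relabeling conditions on the observed value
multiset, so when the field genuinely contains hotspots the permuted
fields retain their heavy tail and greedy regrowth reassembles
patch-level z from scattered values, leaving true patches only
borderline significant (p ≈ 0.01–0.06 at the default scenario's
contrast) — AMOEBA's recall is consequently bimodal across replicates.
Both behaviours follow from the method's design; the alternative
multinomial (case re-scattering) null is hotter still, because it
spreads the hotspot mass over all cells.

## Significance conventions

All Monte Carlo p-values use (1 + r)/(1 + N) with ties counted toward
the numerator, so p ∈ (0, 1] and the test is conservative under
discreteness.  The default null is relabeling of cell values across
units (conditional on the observed multiset); a multinomial
re-scattering of individual cases is available for count totals.  Every
stochastic entry point takes an explicit seed; identical inputs and
seeds give identical outputs, including byte-identical CLI artifacts.

## Synthetic scenarios

The generator emulates a benchmark design: a 30 × 40 raster, i.i.d.
Poisson(λ = 3) background, and four planted clusters totalling 279
cells — (a) a quasi-circular blob (69 cells), (b) an elongated sinuous
band (63), (c) a concave C-shaped annulus-with-gap (75), (d) a compact
blob with a one-cell-wide tail (72) — kept pairwise ≥ 2 cells apart so
no two patches touch under queen adjacency.  The exact published patch
coordinates are not recoverable, so the templates are deterministic
geometric stand-ins matching the stated archetypes and total.  Planted
cells draw from Poisson(λ) conditioned on X ≥ q with q the smallest
integer whose CDF reaches 1 − tail_q (q = 6 at λ = 3, tail_q = 0.05),
sampled by exact inverse-CDF; background cells draw Poisson(λ)
unconditionally.  Expected total ≈ 921·3 + 279·E[X | X ≥ 6] ≈ 4605
cases.

What the generator does **not** emulate: population heterogeneity
(risk is uniform), spatial autocorrelation in the background (counts
are i.i.d.), boundary units of unequal area, and temporal structure.
Passing benchmarks here therefore says nothing about confounding by
population density, which real count data always carries — with a real
population layer the scan's population-weighted μ should be used.

`run_benchmark` replays the four-detector comparison over replicates:
per replicate it samples a scenario, runs each detector at α = 0.05,
and evaluates against the planted truth.  Replicate and method seeds
derive from one master seed through a spawning sequence.  Default
problem sizes (20 replicates, n_sim = 99 for the two Monte Carlo
detectors) keep a full benchmark to a few minutes on one core; n_sim
for a single analysis defaults to 999.

## Evaluation

Indicators are computed from raw sums (cases in flagged cells, flagged
area, patch perimeters); DCR is undefined (NaN, never a number) when
the hotspot covers all cases or the whole area, and an empty labeling
reports the a = 0 sentinel with undefined PAI/DCR/SSI.  SSI uses the
summed perimeter and summed area over all patches.  Reports keep full
precision; `summary()` rounds for display (percentages to 1 decimal,
PAI/DCR to 2, F1/SSI to 3).

## Numerical choices

Scan LRs are computed and compared in log space (raw LRs overflow for
large counts); window tables are precomputed once and reused across the
permutation null.  Distance comparisons carry a 1e-12 slack so exact
lattice distances are not split by floating error.  Ties in scan
windows prefer smaller member sets then lower centre ids; ties in
frontier sorting prefer higher values then lower unit ids.  BH
adjustment passes NaN p-values through untouched.  Degenerate inputs
(constant fields for variance-based statistics, zero total counts for
the Monte Carlo detectors, empty member sets for perimeters) raise
errors or flag NaN as documented per function.

## Known limitations

* The scan supports circular windows and the Poisson model only.
* AMOEBA area-wise false-positive control and power are limited as
  described above.
* Irregular-lattice support covers polygon adjacency, perimeter and
  I/O; the scan's circular windows use centroid distances, which is a
  coarse approximation when polygon sizes vary strongly.
* No coordinate reference system handling: coordinates are assumed
  planar in a common length unit.
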