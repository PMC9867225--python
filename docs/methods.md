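# Methods

## The model

A cultivated-land system is scored per evaluation cell (default 5 km × 5 km,
2500 hm²) and year by a composite index

    CLSHI = Σ_j z_j · w_j ,   z_j ∈ [0, 1],  Σ_j w_j = 1,

over a pressure–state–response indicator hierarchy whose state layer is the
vigor–organization–resilience triad. Nineteen of twenty-seven candidate
indicators carry weight (the packaged registry in `indicators.REGISTRY`
records all twenty-seven with direction, layer, factor group, and the
published comprehensive weight of the retained ones). Pressure indicators
are cost-direction: after the direction-aware normalization a *high*
pressure sub-index means *little* pressure. Because that reading is easy to
invert by accident, the health surface carries both `pressure_index` (benefit
oriented) and `raw_pressure = 1 − pressure_index`.

Assumptions worth stating explicitly:

* county statistics are uniform within a county, so area weighting
  (`Y_i = Σ_j a_ij X_j / Σ_j a_ij`) is exact disaggregation; real
  populations concentrate on construction land, which this model ignores;
* the four ecosystem-service response indicators and biological abundance
  are all proportional to a cell's cultivated area, so they are mutually
  redundant by construction (see *Weighting* below);
* grades from one pooled Fisher–Jenks fit are comparable across years —
  the premise behind the inter-period difference and transition analysis.

## Stage-by-stage choices

**Disaggregation.** The overlap-normalized denominator `Σ_j a_ij` is used
rather than the sum of full county areas: it is the only normalization under
which a cell fully inside a county inherits the county value and every cell
value is a convex combination of county values. The full-county-denominator
variant is available as `strict_literal=True` for comparison; it deflates
cells that touch large counties.

**Indicators.** The biological-abundance formula uses only the
cultivated-land term of the HJ/T192 index (class weight 0.11,
normalization coefficient 511.2642131067); forest/grass/water terms are out
of scope on a cropland-only study. The 1/7 factor in the grain baseline
`E_j = (1/7) Σ a_i P_i Q_i / A` is the fixed national equivalent-factor
convention, not configurable — it is what makes the published baseline of
2581.143 yuan/hm² reproducible from yield 6546.377 kg/hm² × price
2.76 yuan/kg. The nine base service ratios (grain 1.00 … aesthetic 0.17) are
derived constants, recovered by dividing each published coefficient by the
baseline. The baseline's unit is treated as yuan/hm² (the dimensionally
consistent reading of a price × yield product).

**Weighting.** Normalization pools all cells and years per indicator
(`z = (x − min)/(max − min)`, reversed for cost indicators), so a single
PCA/CRITIC run covers the whole panel; stored extrema allow inverse
mapping. PCA runs on the correlation matrix of normalized values. The
screening rule keeps components until cumulative explained variance reaches
`variance_target` (default 0.80) and retains an indicator iff some retained
component gives it an absolute loading ≥ `loading_threshold` (default 0.5) —
it removes low-communality indicators, not redundant ones. The PCA weight of
an indicator is its squared loadings on the Kaiser components (eigenvalue
≥ 1) mixed by the components' variance shares; this construction is
symmetric, scale-free, and reproducible, which is why it was chosen among
the several conventions in use. CRITIC weights are
`C_j = σ_j Σ_k (1 − r_jk)` normalized; the comprehensive weight is the
renormalized mean of the two vectors.

Because the service-value indicators are exact multiples of cultivated area,
the full correlation matrix is singular and KMO is undefined on it. The
diagnostics then fall back to one representative per perfectly-correlated
group (recorded under `kmo_on` in the diagnostics), while screening and
weighting run on the full set — PCA and CRITIC both tolerate the
singularity, and the redundant indicators end up sharing weight, mirroring
the published table where the four service indicators carry one identical
weight. A `fixed_weights` mode bypasses the machinery entirely and injects a
given weight table (renormalized), for exact downstream reproduction.

**Grading.** `jenks_breaks` is the exact Fisher dynamic program (O(k n²),
vectorized inner minimization), verified in tests against exhaustive
enumeration of all partitions for n ≤ 12. Intervals are right-closed: a
value equal to an interior break belongs to the lower class; values outside
the fitting range are clamped with a warning. One pooled fit over all
cell-years is the default (`classification.pooled`), per-year fits are a
flag away.

**Spatial statistics.** The weight schemes are queen contiguity
(row-standardized) for global/local Moran and a fixed distance band of
1.5 × cell size including the focal cell (binary) for Gi*; both are
configurable, and these defaults are standard practice for lattice data.
Inference uses 999 permutations by default — random relabeling for the
global test, conditional permutation (focal value held out, one shared
permutation pool across cells) for LISA. Pseudo-p values are two-sided on
the absolute statistic, `p = (#{|stat*| ≥ |stat|} + 1)/(perm + 1)`; for the
LISA labels this makes the per-cell false-positive rate ≈ α under
exchangeability, which the test suite checks empirically (200 white fields).
Gi* is the ratio form with the closed-form Getis–Ord randomization moments
for its z-score; a constant field raises an undefined-statistic error rather
than returning zeros.

**Zoning.** Grade arithmetic maps I→1 … V→5 and defines improvement as
start − end > 0. The five-zone rule is a total function of the level
difference, so the two transition codes never observed in practice (15, 51)
are still assigned (priority and moderate respectively) instead of being
rejected. Printed-table comparisons use half-up rounding to two decimals
(`zoning.round_half_up`), matching how such tables are typeset.

## The synthetic generator

The generator emulates the study's four inputs with known embedded
structure. County geometry is rasterized — counties are Voronoi patches of
fine sub-cells (default 10 × finer than the grid) — so overlap areas are
exact sub-cell counts and the conservation law `Σ_i a_ij = A_j` holds to the
bit, with no computational-geometry dependency. Spatially correlated fields
are Gaussian-smoothed white noise (configurable kernel radius, re-standardized),
plus deterministic Gaussian bumps at the planted high/low-health cluster
centers; with kernel radius 0 the field is spatially white, the null case
for the autocorrelation tests. All randomness flows from one root seed
through named substreams (`crc32`-derived child keys), so each product is
independently reproducible.

Default study conditions, chosen once as plausible for an intensively farmed
alluvial plain and kept fixed: 30 × 30 cells of 5 km (900 cells — a
desk-scale stand-in for a multi-thousand-cell study), 12 counties, five
years 2000–2019, one high- and one low-health cluster (amplitude ±2 z,
radius 4 cells, correlation range 2 cells), NPP 500 ± 80 gC/m²/yr declining
2 gC/m²/yr/yr, NDVI 0.62 ± 0.08, cultivated fraction 0.55 ± 0.18 of a cell
(static over years), and twelve raw panel indicators whose means, trends and
noise are listed in `config.default_indicator_specs` — pressures rising,
several state/response indicators declining, so the composite index of the
default scenario drifts downward.

What the generator does *not* emulate: realistic administrative geography,
within-county heterogeneity of statistics, land-cover class mixtures beyond
a single cultivated fraction, measurement error structure of real yearbooks,
and year-to-year reallocation of cropland. Passing tests therefore
demonstrate the correctness and calibration of the *methods* on data with
known truth, not the reproduction of any real region's results.

## Numerical notes

* CSV is the canonical interchange; floats are serialized with 17
  significant digits, so write→read round-trips to 1e-12 and reruns are
  byte-identical (the end-to-end determinism test compares raw bytes).
* Jenks ties are broken toward the earliest split; `argmin` order makes the
  Voronoi county assignment deterministic under centroid ties.
* Degenerate inputs fail loudly: constant indicators (normalization),
  singular correlation beyond the duplicate-group fallback (KMO), zero
  variance fields (Moran/Gi*), fewer distinct values than classes (Jenks),
  cells with zero overlap (disaggregation).
* Derived permutation seeds are 31-bit, so any integer root seed is safe.

## Known limitations

* The PCA weighting recipe is one of several reasonable conventions; with
  `fixed_weights` the rest of the pipeline is convention-independent.
* LISA p-values share one permutation pool across cells (standard practice);
  p-values of neighboring cells are therefore correlated.
* The pooled Jenks grades change if the pooled sample changes — adding a
  year re-grades all years; per-year mode avoids this at the cost of
  cross-year comparability.
* `strict_literal` disaggregation exists for comparison only; its outputs
  are not convex combinations of county values and should not feed the
  index.
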