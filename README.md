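# clsh — cultivated-land system health evaluation

`clsh` evaluates the health of a cultivated-land system on a regular grid of
evaluation cells, for landscape ecologists and land-use planners who work
with county-level statistical panels and gridded remote-sensing products.
It implements a pressure–state–response (PSR) indicator hierarchy whose
state layer follows the vigor–organization–resilience (VOR) triad, and takes
a study from raw inputs to a regulation map in seven stages:

1. **simulate** — a seeded synthetic-data generator that emulates every
   input (county polygons with exact overlap areas, a county statistical
   panel, NPP/NDVI rasters, a grain yield/price table) with planted spatial
   clusters and temporal trends, so the whole chain is testable without
   proprietary data;
2. **disaggregate** — county statistics are mapped to cells by area
   weighting, `Y_i = Σ_j a_ij X_j / Σ_j a_ij`, with a total-land overlap
   variant for population/economic densities and a cultivated-land variant
   for per-cultivated-area intensities;
3. **indicators** — formula-based state/response indicators: cultivated-land
   productivity `P_i = N̄PP_i · A_i`, the HJ/T192 cultivated-land
   biological-abundance term `I_bio = A_bio · 0.11 · a_i / A_i`
   (`A_bio = 511.2642131067`), and equivalent-factor ecosystem-service
   values scaled off the grain baseline `E_j = (1/7) Σ_i a_i P_i Q_i / A`;
4. **weights** — direction-aware min–max normalization pooled over all
   cell-years, KMO/Bartlett diagnostics, PCA loading-based screening, then
   the average of PCA and CRITIC objective weights
   (`C_j = σ_j Σ_k (1 − r_jk)`), normalized to sum 1;
5. **health** — the composite index `CLSHI = Σ_j z_j w_j ∈ [0, 1]`
   (higher = healthier) plus layer sub-indices, graded I (best) to V (worst)
   by exact Fisher–Jenks natural breaks on the pooled sample;
6. **spatial** — global Moran's *I* with permutation inference and scatter
   quadrants, local Moran (LISA) cluster labels under conditional
   permutation, and Getis-Ord Gi\* hot/cold-spot surfaces with a
   Jenks 5-level classification of the z-scores;
7. **zoning** — per-class area accounting, inter-period variation and change
   rates, two-digit grade-transition codes (start grade then end grade), and
   five regulation zones assigned by the level difference
   Δ = start − end: Δ ≥ 2 moderate optimization, Δ = 1 collaborative
   optimization, Δ = 0 potential promotion, Δ = −1 key promotion,
   Δ ≤ −2 priority promotion.

## Worked example

The ecosystem-service baseline from regional grain averages (yield
6546.377 kg/hm², price 2.76 yuan/kg):

```python
>>> import pandas as pd
>>> from clsh import grain_economic_value, revise_esv_coefficients
>>> crops = pd.DataFrame({"crop": ["grain"], "area_hm2": [1.0],
...                       "yield_kg_per_hm2": [6546.377],
...                       "price_yuan_per_kg": [2.76]})
>>> round(grain_economic_value(crops, 1.0), 3)
2581.143
>>> revise_esv_coefficients(2581.143).tail(2)
                    service  base_ratio  coefficient_yuan_per_hm2
7  biodiversity_maintenance        1.02                2632.76586
8       aesthetic_landscape        0.17                 438.79431
```

`grain_economic_value` returns one-seventh of the grain market value per
hectare — the standard-equivalent unit — and `revise_esv_coefficients`
rescales the nine farmland service ratios onto that local baseline.

The full pipeline on the default synthetic study (a 30 × 30 grid of 5 km
cells, 12 counties, five years 2000–2019):

```sh
$ clsh run-all --out results/demo --seed 1
pipeline complete: results/demo
```

Key outputs (from `timeseries_summary.csv`, `moran.json`,
`zone_statistics.csv` of that run):

* mean CLSHI drifts from 0.5116 (2000) to 0.5054 (2019) — the generator's
  rising-pressure, declining-response trends push composite health down;
* global Moran's *I* of the index is 0.941 → 0.938 (pseudo-p = 0.001 at 999
  permutations): the planted high/low-health clusters make the surface
  strongly positively autocorrelated;
* 88.2 % of cultivated area falls in the stable "potential promotion" zone,
  the rest in the one-grade-change zones, because most cells keep their
  pooled Jenks grade between the endpoint years.

Each stage can also be run separately (`clsh simulate`, `clsh disaggregate`,
…, `clsh zoning`) on the same working directory, and `clsh write-config`
dumps the default YAML configuration for editing.

## Layout

```
src/clsh/        synthetic.py, disaggregation.py, indicators.py,
                 weighting.py, health.py, spatial.py, zoning.py,
                 pipeline_io.py, config.py, cli.py
tests/           unit + property suites and tests/test_acceptance.py
docs/methods.md  model, assumptions, parameter choices, limitations
```
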