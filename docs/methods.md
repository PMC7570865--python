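# Methods

This document records the model implemented by `fireval`, the numerical
choices made, and the known limitations. Notation: BA = burned area,
CE = commission error, OE = omission error, P = detected fraction of the
reference burned area, TE = total error, AUPB = area under the Pareto
boundary.

## 1. Grid model and rasterization

A `GridSpec` describes an axis-aligned raster with its origin at the
**upper-left** corner, square pixels of side `pixel_size` metres, and
`n_rows × n_cols` pixels. The default validation grid uses 50 m pixels
(0.25 ha each), fine enough that perimeter digitization error, not pixel
size, dominates the reference uncertainty.

Reference fire perimeters (shapely polygons, planar map coordinates in
metres) are rasterized under the **maximum-area rule**: a pixel is labelled
Burned when the polygon covers at least half of its area. Coverage is
computed by exact polygon–pixel intersection (shapely), not point sampling.
The 0.5 comparison uses a tolerance of 1e-9 on the covered fraction and
resolves exact ties to Burned, so a polygon covering exactly half a pixel
burns it. The test suite checks this against an independent 10×10
supersampling oracle. Geometries falling partly outside the grid raise a
warning; invalid geometries raise `GeometryError`.

`BurnGrid` stores the binary map (uint8, {0, 1}) plus an optional year.
Multiple per-fire grids are combined with `union_grids` (logical OR),
consistent with perimeters that may overlap.

## 2. Aggregation to product resolution

`aggregate_fraction(grid, factor)` block-averages the 50 m binary map into a
burned-fraction grid at `factor × 50` m (e.g. factor 5 → 250 m, factor
10 → 500 m), implemented as a reshape-mean. Aggregation conserves burned
area to floating-point tolerance; the suite asserts conservation at
`rel=1e-9` over 1000 random grids. When the fine grid's dimensions are not
divisible by the factor, the grid is zero-padded on the right/bottom and a
`padded_mask` marks coarse cells containing padding; padded cells dilute the
fraction, which is the conventional treatment of a study-area edge.

## 3. Spatial accuracy

From a product map and a reference map on the same `GridSpec`,
`confusion_counts` tallies

|                     | reference Burned | reference Unburned |
|---------------------|------------------|--------------------|
| product Burned      | n11              | n12                |
| product Unburned    | n21              | n22                |

with marginals n1c = n11+n12 (product burned), n1r = n11+n21 (reference
burned), n2r = n12+n22 (reference unburned). Derived metrics:

- OA = (n11 + n22) / n
- CE = n12 / n1c — fraction of the product's burned pixels that are wrong
- OE = n21 / n1r — fraction of the reference burned pixels that are missed
- S = 1 − OE (sensitivity), Sp = n22 / n2r (specificity; true non-burned
  over **reference** non-burned)

Conventions for degenerate margins: an empty product (n1c = 0) has CE := 0
(it commits nothing); an empty reference (n1r = 0) has OE := 0 and emits a
warning, since validation against an empty reference is rarely meaningful.
An all-zero matrix is rejected.

### Total error

TE = CE · P + OE, with P = BA_product / BA_reference. CE is weighted by P
because commission is expressed relative to the *product's* burned area;
multiplying by P converts it to the reference-area scale so both terms are
commensurable. TE can exceed 1 (e.g. a product that misses everything,
OE = 1, while also burning pixels outside the reference, CE > 0).
`total_error_ha` gives the equivalent in hectares:
TE_ha = CE · BA_product + OE · BA_reference.

`weighted_error_summary` combines per-year rows into a multi-year summary:
CE and OE are averaged with reference-burned-area weights,
P = ΣBA_product / ΣBA_reference, and TE is recomputed from the summary CE,
OE and P (not averaged), so the identity holds exactly at every level.

## 4. Temporal accuracy

Annual percentage P% = 100 · BA_product / BA_reference per year; years with
zero reference area are skipped in the multi-year weighted average
Σ(BA_ref,y · P%_y) / ΣBA_ref,y. The coefficient of determination R² between
annual product and reference burned areas is the squared Pearson correlation
(`np.corrcoef`). Fires are additionally binned into five size classes,
half-open on the right:

| class       | area (ha)          |
|-------------|--------------------|
| very_small  | [0, 100)           |
| small       | [100, 1,000)       |
| medium      | [1,000, 10,000)    |
| large       | [10,000, 100,000)  |
| very_large  | [100,000, ∞)       |

## 5. Pareto boundary and AUPB

Given a burned-fraction grid f at the product resolution, each threshold p
defines a classification B(p) = {f ≥ p} for p > 0 and {f > 0} for p = 0
(any trace of fire counts at the permissive end). Area-based errors:

- CE(p) = Σ_{B} (1 − f) / |B| — unburned area inside the classification,
  per classified cell
- OE(p) = Σ_{∉B} f / Σ f — burned area left outside, relative to total

The sweep is vectorized with sorted fractions and prefix sums. Duplicate
(CE, OE) points are removed and dominated points discarded, leaving a
strictly decreasing OE(CE) — the Pareto boundary: no real product at this
resolution can beat it in both errors simultaneously. **AUPB** is the area
under this curve by the trapezoidal rule; higher AUPB = a harsher
resolution-induced error floor. AUPB is a property of the reference
landscape and the resolution only; no product enters its computation.

`pareto_boundary(frac, n_steps)` accepts an integer number of equidistant
thresholds (default 101, i.e. steps of 0.01 over [0, 1]) or `"exact"`,
which sweeps every distinct positive fraction and appends p = 1.0 when the
maximum fraction is below 1, so the empty-classification anchor (CE = 0,
OE = 1) is always represented. With the exact sweep the curve is
step-size-independent; the suite asserts that a 1001-step sweep coincides
with the exact sweep on 200 random grids.

`fit_te_vs_aupb` regresses annual TE on annual AUPB by ordinary least
squares (`scipy.stats.linregress`), returning slope, intercept, R² and n.
On the packaged Alaska tables this reproduces the published fit
(slope ≈ 63.1, R² ≈ 0.45) for the 250 m product with 16 usable years.

## 6. Synthetic landscape generator

`generate_landscape` places non-overlapping contiguous fire scars on a
`GridSpec`:

- **Sizes** are drawn log-uniformly within each requested size class (or
  given explicitly via `fire_sizes_ha`), converted to a whole number of
  pixels. `annual_total_target_ha` rescales the drawn sizes to hit an
  annual total.
- **Shape**: each scar grows by Eden-type accretion — starting from a seed
  pixel, unburned 4-neighbours of the current scar are added one at a time,
  chosen uniformly from the frontier. This yields compact, irregular,
  simply-connected blobs resembling wind-driven scars' rough edges, without
  modelling fire spread physics.
- **Packing**: fires are placed largest-first with retries (default 50);
  total burned pixels are capped at `max_fill` (default 0.5) of the grid,
  and exceeding capacity raises `InfeasiblePackingError` with the requested
  and achievable pixel counts.
- Optionally (`build_polygons`), each scar's pixel footprint is unioned
  into a shapely polygon so the rasterization path can be exercised
  round-trip.

`perturb_product` degrades a reference map into a simulated product with
target CE ∈ [0, 1) and OE ∈ [0, 1]:

- **Omission** removes `round(OE · n_ref)` reference pixels — uniformly at
  random, or in `perimeter_first` mode by peeling successive edge layers
  (binary erosion), emulating products that miss fire edges.
- **Commission** adds `n_add = round(CE · kept / (1 − CE))` unburned pixels
  so that the realized n12/n1c matches the target — uniformly, or in
  `perimeter_first` mode by accreting a ring around the reference scar
  (dilation of the scar plus already-added pixels), emulating
  over-detection at fire margins.

The rounding to whole pixels is the only source of deviation: on a 5000-px
scar the suite recovers every combination of CE ∈ {0.05, 0.15, 0.5} ×
OE ∈ {0.1, 0.4, 0.7} in both modes within ±0.01 over 20 seeds.

`generate_multiyear` derives each year's RNG from
`np.random.SeedSequence([master_seed, year])`, so years are independent,
reproducible, and insensitive to the order of generation. A year with no
fires yields an empty reference and an empty product (not an error).

What the generator does **not** emulate: real fire-spread physics, fuel or
topography, unburned islands inside scars, multi-year reburns, cloud/smoke
observational gaps, or spatially correlated product noise beyond the
perimeter-first patterns.

## 7. Reporting

`run_assessment(AssessmentConfig)` takes per-year reference grids and one
or more products, computes per-year confusion metrics, TE, annual
percentages, AUPB per aggregation factor, multi-year weighted summaries,
and (when a product has ≥ 3 years and a designated factor) the TE-vs-AUPB
regression. `report_tables` writes fixed-format CSVs (percent at 2 dp,
errors at 3 dp, AUPB × 1000 at 3 dp) plus a full-precision JSON bundle;
output is byte-for-byte deterministic. `recompute_te_table` checks the
TE identity over a published table, reporting the maximum deviation after
rounding P to 4 decimal places (the precision of a percentage printed to
2 dp); on the packaged tables the maximum deviation is 0.000 across all 63
cells.

The packaged tables (`fireval.datasets`) cover four 250/500 m BA products
over 18 fire seasons: annual detected percentages, annual and multi-year
CE/OE/TE with burned areas, and annual AUPB at 250 m and 500 m. Years are
stored as strings with `"all"` for the multi-year rows.

## 8. Problem sizes and performance

Defaults were chosen so a laptop handles realistic cases comfortably: the
acceptance tests use 300×300 (15 km × 15 km) to 400×400 grids at 50 m,
5000-pixel scars, 1000-grid conservation sweeps and 100-landscape AUPB
monotonicity sweeps; the whole suite runs in ~15 s. The sweep and
aggregation are O(n log n) and O(n) in pixel count; multi-million-pixel
grids are practical.

## 9. Known limitations

- Planar coordinates only; no CRS handling or reprojection. Inputs must
  already share a projected, metre-based coordinate system.
- Rasters are exchanged as plain TIFF or ESRI ASCII with a JSON sidecar
  for georeferencing/metadata, not as fully georeferenced GeoTIFF.
- The maximum-area rule is applied per polygon before unioning, so two
  fires each covering 30 % of the same pixel leave it Unburned; this
  mirrors per-perimeter rasterization practice but differs from
  rasterizing the unioned geometry.
- AUPB compares resolutions on the same landscape; comparisons across
  different landscapes conflate landscape fragmentation with resolution.
- The weighted multi-year summary recomputes TE from summary CE, OE, P;
  it is not the area-weighted mean of annual TE values (the two differ
  when P varies across years).
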