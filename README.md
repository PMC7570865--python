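# fireval

Accuracy assessment of gridded burned-area products against fire-perimeter
reference data.

Satellite burned-area (BA) products map where fire occurred each year, but in
boreal regions their agreement with high-quality reference perimeters (e.g.
agency fire-perimeter databases) is often poor. `fireval` implements the
standard validation workflow used in such assessments, plus a synthetic
fire-landscape simulator for testing the workflow end to end:

- **Rasterization** of reference fire perimeters to a fine binary grid
  (50 m pixels, 0.25 ha) under the maximum-area rule: a pixel is Burned when
  at least half of its area is covered.
- **Spatial accuracy**: pixel-level confusion matrix and the derived metrics
  — overall accuracy (OA), sensitivity (S), specificity (Sp), commission
  error (CE) and omission error (OE) — and the **total error**

  &nbsp;&nbsp;&nbsp;&nbsp;TE = CE · P + OE

  where P is the fraction of the reference burned area detected by the
  product. TE expresses the combined mapping error relative to the reference
  burned area and may exceed 1 when a product both misses most of the fire
  and commits heavily.
- **Temporal accuracy**: annual detected percentage
  P% = 100 · BA_product / BA_reference, its multi-year reference-area-weighted
  average, and the coefficient of determination between annual product and
  reference areas.
- **Pareto boundary analysis**: for a product grid coarser than the
  reference, the boundary of the lowest jointly achievable (CE, OE) pairs is
  obtained by sweeping a threshold over the aggregated burned-fraction grid.
  The **area under the Pareto boundary (AUPB)**, computed by the trapezoidal
  rule, quantifies the error floor imposed by the coarse resolution alone;
  larger AUPB means the resolution itself prevents accurate mapping.
- **Synthetic landscapes**: contiguous fire scars drawn from five size
  classes, degraded into simulated products with controlled CE/OE rates
  (uniform or perimeter-first spatial patterns), for validating that the
  metrics recover known error rates.
- **Reporting**: a `fireval` CLI and a `run_assessment` API that produce
  per-year and summary tables (CSV + JSON).

Intended users are remote-sensing and fire-ecology researchers validating BA
products, and developers of such products who need a reproducible error
baseline.

## Quick start

Simulate a small fire season, degrade it into a product with 15 % commission
and 40 % omission, and score it:

```python
from fireval import (GridSpec, LandscapeConfig, PerturbConfig,
                     generate_landscape, perturb_product, confusion_counts,
                     metrics, total_error, aggregate_fraction,
                     pareto_boundary, burned_area_ha)

spec = GridSpec(0.0, 300 * 50.0, 50.0, 300, 300)        # 15 km x 15 km at 50 m
cfg = LandscapeConfig(spec=spec, n_fires={"very_small": 3, "small": 2},
                      seed=7, build_polygons=False)
events, ref = generate_landscape(cfg)

prod = perturb_product(ref, PerturbConfig(target_CE=0.15, target_OE=0.40,
                                          spatial_mode="perimeter_first", seed=7))
m = metrics(confusion_counts(prod, ref))
P = burned_area_ha(prod) / burned_area_ha(ref)
print(f"CE = {m.CE:.3f}, OE = {m.OE:.3f}, P = {P:.3f}")
print(f"TE = {total_error(m.CE, m.OE, P):.3f}")

curve = pareto_boundary(aggregate_fraction(ref, 5), 101)  # 250 m product grid
print(f"AUPB at 250 m: {curve.aupb:.5f}")
```

Output:

```
CE = 0.150, OE = 0.400, P = 0.706
TE = 0.506
AUPB at 250 m: 0.05118
```

The injected error rates are recovered exactly, and the AUPB quantifies how
much error a perfect 250 m product of this landscape would still incur.

The package also ships the published Alaska assessment tables
(`fireval.datasets`). Regressing each year's total error of a 250 m product
against that year's AUPB at 250 m reproduces the published relation between
resolution-induced error and realized error:

```python
from fireval import fit_te_vs_aupb
from fireval.datasets import load_error_metrics, load_aupb

errors = load_error_metrics()
au = load_aupb().set_index("year")
sub = errors[(errors["product"] == "Fire_CCI_5.1")
             & (~errors["year"].isin(["2000", "2001", "all"]))]
pairs = [(au.at[y, "res_250m"] / 1000.0, te)
         for y, te in zip(sub["year"], sub["TE"])]
fit = fit_te_vs_aupb(pairs)
print(f"TE = {fit.slope:.2f} * AUPB + {fit.intercept:.2f}   "
      f"(R^2 = {fit.r_squared:.3f}, n = {fit.n})")
```

Output:

```
TE = 63.15 * AUPB + 0.36   (R^2 = 0.455, n = 16)
```

### Command line

```bash
fireval simulate --rows 300 --cols 300 --fires very_small=3 --fires small=2 \
    --seed 7 --target-ce 0.15 --target-oe 0.40 --out sim/
fireval pareto --reference sim/reference.asc --factor 5 --out pareto.csv
fireval assess --config assessment.json --out report/
```

See `fireval --help` and `docs/methods.md` for details.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) and brute-force oracles
for rasterization and the Pareto sweep; it runs in well under a minute.

## Layout

- `src/fireval/grid.py` — grid model, rasterization, aggregation
- `src/fireval/spatial.py` — confusion matrix, CE/OE/OA/S/Sp, total error
- `src/fireval/temporal.py` — annual percentages, weighted averages, R²
- `src/fireval/pareto.py` — Pareto boundary, AUPB, TE-vs-AUPB regression
- `src/fireval/synthetic.py` — landscape generator and product degradation
- `src/fireval/report.py`, `src/fireval/cli.py` — assessment runs and CLI
- `src/fireval/data/` — packaged published assessment tables
- `docs/methods.md` — model, numerical choices, and limitations
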