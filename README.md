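# popdis — top-down population disaggregation with multi-level validation

`popdis` is for researchers who turn aggregated census counts into gridded
or building-level population maps and want to know *how much to trust
them*. It implements the full experimental machinery of a top-down
disaggregation study: five allocation methods, the geospatial covariate
engineering behind statistical weight layers, occupancy-weight
calibration, a 36-scenario design matrix spanning poor- to rich-data
conditions, and a two-fold validation that scores every map at two nested
census levels — including the over-/under-estimation errors that only
non-contiguous block-level validation can reveal. A seeded synthetic-city
generator provides complete test beds with known building-level ground
truth.

## The methods

Population `P_sz` known at source zones (SZ) is redistributed to target
zones (TZ: urban pixels, buildings, or 100 m grid cells), always
mass-preserving per SZ (the *pycnophylactic* property):

- **binary dasymetric** `P_tz = A_tz · P_sz / Σ A_tz`, with `A_tz` the
  urban area or building size (footprint × floors) of the TZ inside the SZ;
- **categorical dasymetric** adds land-use occupancy weights `W_lu`
  (residential = 1; commercial/other calibrated by grid search):
  `P_tz = (A_tz·W_lu)·P_sz / Σ(A_tz·W_lu)`;
- **statistical** fits a random forest (500 trees, 3 variables per split,
  leaf size 5) of population density at SZ level and predicts a per-cell
  weight layer `W_p`: `P_cell = W_p·P_sz / Σ W_p`;
- **combined** variants constrain the statistical weights to the urban
  mask: `P_tz = (A_tz·[W_lu·]W_p)·P_sz / Σ(…)`.

Maps are validated by aggregating TZ estimates into validation zones and
computing R², normalized RMSE, RTAE (total absolute error / total
population), MAPE (positive-population units), and the underestimation /
overestimation shares UE / OE. Error structure is analysed through
per-unit absolute percentage errors grouped by dominant land use and by
area/density quartiles, compared with Wilcoxon rank-sum tests.

See `docs/methods.md` for the full model description, parameter defaults
and numerical conventions.

## Worked example

```python
from popdis import (generate_city, ExperimentContext, OccupancyWeights,
                    design_matrix, run_experiment)

city = generate_city(seed=1)                  # 4x4 km synthetic city
ctx = ExperimentContext(city)
spec = {s.id: s for s in design_matrix(base_seed=1)}["E6"]
res = run_experiment(spec, city, occupancy=OccupancyWeights(w_C=0.4, w_O=0.3),
                     context=ctx)
r1, r0 = res.report_l1, res.report_l0
print(f"city: {len(city.buildings)} buildings, "
      f"{city.zones_l2.total_population():.0f} inhabitants")
print(f"  L1: R2={r1.r2:5.1f}%  NRMSE={r1.nrmse:5.1f}%  RTAE={r1.rtae:5.1f}%")
print(f"  L0: R2={r0.r2:5.1f}%  RTAE={r0.rtae:5.1f}%  OE={r0.oe:4.1f}%")
```

prints

```
city: 3826 buildings, 138071 inhabitants
  L1: R2= 98.0%  NRMSE= 14.4%  RTAE=  8.9%
  L0: R2= 93.1%  RTAE= 18.7%  OE= 0.0%
```

E6 is the categorical dasymetric method on the 3D land-use building mask —
the richest-data scenario. The L1 row says the map explains 98% of the
section-level population variance with a total misallocation of 8.9% of
the population; the L0 row shows that even at the block level the
allocation holds up (R² 93%), with essentially no population placed in
unpopulated blocks (OE ≈ 0). Running the statistical method instead
(`E9`) keeps the L1 scores close but collapses at L0 with OE ≈ 14% — the
validation-level illusion this package is built to expose.

The same pipeline is scriptable from the shell:

```bash
popdis generate --seed 1 --out bundle/           # write a city bundle
popdis search-occupancy --bundle bundle/         # calibrate (w_C, w_O)
popdis run --bundle bundle/ --experiments all --out results/
popdis report --results results/
```

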