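# Methods

`popdis` implements top-down population disaggregation: census counts known
at coarse *source zones* (SZ) are redistributed to fine *target zones* (TZ
— urban raster pixels, building footprints, or 100 m grid cells) using
auxiliary geospatial data, and the resulting maps are scored against nested
*validation zones* (VZ) whose counts were withheld from the methods.

## Disaggregation methods

All methods share one allocation kernel and are *pycnophylactic*: for every
SZ the allocated TZ populations sum exactly (to float precision) to the
census count. A TZ straddling an SZ boundary receives an area-proportional
contribution from each side. Five methods are provided:

1. **Binary dasymetric** — allocation weight is the TZ's habitable size
   inside the SZ: urban area (AREA) or building size = footprint area ×
   floors (VOLUME),
   `P_tz = A_tz · P_sz / Σ A_tz`.
2. **Categorical dasymetric** — the size is additionally multiplied by a
   land-use occupancy weight `W_lu` with residential fixed at 1:
   `P_tz = (A_tz · W_lu) · P_sz / Σ (A_tz · W_lu)`.
   With a single land use in an SZ this reduces exactly to the binary form.
3. **Statistical** — a random-forest regression (500 trees, 3 variables per
   split, minimum leaf size 5) is fitted at SZ level with population
   density (persons / m² of unit area, untransformed) as the response and
   the geospatial covariates as predictors; the prediction on the grid is
   the weight layer `W_p`, and `P_cell = W_p · P_sz / Σ W_p`. Negative
   predictions are clipped to zero and counted. The model's out-of-bag R²
   and normalized RMSE are reported with every run.
4. **Combined binary / categorical** — dasymetric allocation with the
   weight additionally multiplied by the `W_p` of the grid cell containing
   the TZ centroid (the mapping of a 100 m weight onto sub-cell TZs is not
   uniquely defined; centroid lookup is this package's fixed convention).
   With a constant weight layer both variants reduce exactly to the
   corresponding dasymetric method.

**Degenerate SZs.** A populated SZ whose weighted urban area is zero cannot
allocate through the mask. Rather than silently losing mass, the SZ's count
is spread uniformly over its full polygon (one logged fallback TZ row);
the anomaly is reported on the estimate.

**Occupancy calibration.** `search_occupancy_weights` evaluates every
`(w_C, w_O)` pair on a step-0.1 grid (121 pairs), scoring the categorical
method with both the area and the building-size mask using normalized RMSE
and RTAE at both validation levels plus the over-/under-estimation errors
at block level — 12 metric columns. The selected pair minimizes the rank
sum across columns; exact ties break toward higher occupancy and are
flagged. The default city is generated with true `(0.4, 0.3)`; because
some urbanized blocks carry no census population (institutional blocks)
and commercial/other buildings have high occupancy variance, the search is
mildly biased low — typically selecting within one grid step of the truth,
the behaviour expected when census anomalies interact with the calibration.

## Validation

Estimates are aggregated into each VZ unit by proportional-area overlay;
mass falling outside every unit is tracked separately. Seven statistics
(percent): R² (Eq-6 style, can be negative, undefined when the known
counts have zero variance), NRMSE (RMSE / mean VZ population), RTAE (sum
of absolute errors / total population), MAPE (over units with nonzero
population; the number of excluded zero-population units is always
reported), UE (share of true population in units with an estimate below
1e-9), and OE (share of the total population not landing inside VZ units).

Validation is *two-fold*: the same estimate is scored at the contiguous
section level (L1) and at the non-contiguous block level (L0). Only L0 can
see mass allocated to streets and unpopulated land, which is what exposes
the statistical method's flattering L1 scores.

**Error structure.** Per-unit absolute percentage errors (APE, positive-
population units only) are grouped by dominant land use (share > 0.8,
strict; groups: mostly-residential / commercial / other / no-dominant) or
by area / population-density quartiles (linear-interpolation quantiles,
boundary units to the lower quartile). Group differences are tested with
the two-sided Wilcoxon rank-sum test — exact enumeration for tie-free
groups of ≤ 20, normal approximation with tie correction otherwise.

## Covariates

Per spatial unit (SZ or grid cell): densities (apportioned area, floor
area, line length or point count per m² of unit area), mean nearest
distances (target rasterized, Euclidean distance transform, averaged over
cells whose centres fall in the unit; an empty target returns the cap,
defaulting to the extent diagonal), terrain statistics (mean/sd of
elevation and slope by cell-centre membership, population-sd), and nine
landscape metrics of the unit-clipped binary mask (8-connected patches):

| metric | definition (all dimensionless; `A_u` unit area, `r = √(A_u/π)`) |
|---|---|
| MS | mean patch area / `A_u` |
| SI | mean of patch perimeter / (2√(π · patch area)) |
| P | 1 − urban area / convex-envelope area of the urban cells |
| C | mean of 4π · area / perimeter² |
| EMS | Σ patch area² / `A_u`² |
| DO | patch count per km² of unit area |
| DI | mean patch-centroid distance to the joint centroid / `r` |
| ENND | mean nearest-neighbour edge distance between patches / `r` (1 if < 2 patches) |
| AWSDn | area-weighted standard distance of patch centroids / `r` |

Perimeters are edge counts, so the compactness of a rasterized disc
converges to (π/4)² ≈ 0.62, not 1 — a property of the convention, asserted
in the tests. These formulas are fixed conventions of this package;
equivalent metrics in the landscape-ecology literature differ in
normalization details.

Covariate **cases** express data availability per urban mask, from most to
least: **D** = spatial metrics + urban density/distance (+ building-size
density for 3D masks); **C** = D + road axis/intersection covariates;
**B** = C + terrain + vegetation; **A** = B + land-use densities/distances
(zone-polygon based for the raster masks, building-based for footprint
masks, plus per-land-use floor-area densities when floors are available)
+ establishment covariates. Before model fitting, covariates are pruned:
zero-variance columns, columns with |Pearson r| > 0.85 against unit area,
and within any pair with |r| > 0.85 the column less correlated with the
response (greedy, strongest predictor first). Pruning is idempotent; the
0.85 threshold is configurable.

## The synthetic city

The generator emulates a dense, heterogeneous valley city with known
building-level ground truth. Defaults (4 × 4 km): 36 sectors (L2) of
667 m, each split 2×2 into 144 sections (L1), each split 3×3 into 1296
urban blocks (L0) separated by 16 m arterials and 10 m local roads —
blocks own whole buildings (centroid assignment) and are non-contiguous,
while L1/L2 tile the extent. 36 SZs is deliberately larger than a minimal
toy: one row per SZ is all the weight model ever sees, and a forest with
3-way splits needs tens of rows to express any structure.

Buildings occupy ~50 m parcels (log-normal footprints, mean 400 m²;
geometric floor counts, mean 2.5). Population density per m² of floor area
follows a north–south exponential gradient (ratio 8 across the extent,
base 0.03 persons/m² ≈ one person per 33 m² of floor area). Structural
density tracks population density — build probability, floor counts rise
with the gradient, vegetation falls — because covariates can only carry a
density signal if the built fabric does; this is the premise of every
statistical disaggregation. Land use mixes residential/commercial/other
(0.70/0.15/0.15) with a central commercial corridor (600 m) and clustered
"other" pockets; 3% of blocks are institutional: urbanized but with zero
census population. True building population = floor area × density ×
occupancy (1 / 0.4 / 0.3 for R/C/O) × mean-one log-normal noise (σ = 0.25,
plus σ = 0.6 extra variance for C/O mixed use), stochastically rounded to
integers with expectation preserved.

Masks: VHR = the footprints themselves (optionally floor-weighted, 3D;
optionally with land use). HR (3 m) rasterizes the sealed surface —
buildings buffered 8 m (pavement) plus road corridors — at a 0.5 coverage
threshold, with commission noise (rate 0.25) on cells adjacent to urban
coverage and omission noise (rate 0.02) on building-only cells, mimicking
informal settlements missing from a cadastre. MR (30 m) uses a 0.25 purity
threshold: a coarse mixed pixel classifies as urban, the generous behaviour
of medium-resolution land-cover products. Terrain is a cross-valley
parabola with smoothed random relief at 10 m; slope is derived in degrees.

**What the generator does not emulate:** georeferencing error, polygon
slivers and topology defects, non-convex buildings, temporal mismatch
between census and cadastre, multi-nuclei density surfaces, and census
undercount. Passing tests therefore demonstrate correctness of the methods
and the reproducibility of the *relative* findings under clean geometry,
not performance guarantees on any real cadastre.

## Experiments

The design matrix pairs methods with six masks: E1–E6 dasymetric (one per
mask, categorical for the land-use masks, VOLUME for 3D), E7–E12
statistical (case A per mask), E13–E36 combined (cases A–D per mask).
Data-availability labels: poor (E1, E14–E16), average (E2, E7–E8, E13,
E17–E20), rich (the rest); E13 is labelled average, following the result
tables rather than the figure caption that lists it twice. The RF seed of
each experiment is the run seed offset by the experiment index. The
consolidated table has one row per experiment with the RF report and the
full two-fold metric set; re-running against an output directory skips
experiments already recorded under the same bundle content hash.

The **best-reference grid** re-runs the strongest configuration
(categorical dasymetric, VOLUME, land use) with the L0 blocks themselves
as source zones — the best grid achievable with the data — and every
experiment's grid can be scored against it (R², NRMSE, RTAE, residual
raster).

## Numerical conventions

- Planar metric coordinates throughout; no geodesic math, no reprojection.
- Grid cells at a clip boundary are kept whole; the analysis grid is
  padded one cell beyond the extent so overhanging edge pixels of coarse
  masks stay inside it (total population on the grid is conserved).
- Raster cells are square polygons for overlay; terrain and distance
  statistics use cell-centre membership, ties to the smaller unit id.
- Populations stay floating point after disaggregation; rounding only in
  display output.
- Overlay fraction tolerance 1e-9; conservation tolerance 1e-6 relative;
  an estimate below 1e-9 counts as zero for the underestimation error.
- Distance covariates for ancillary layers are computed at 10 m analysis
  resolution; the urban-mask distance uses the mask's native resolution.
- Runtime scale: the default city (≈3.8k buildings, 1296 blocks, 1681
  grid cells) runs the full 36-experiment matrix in about two minutes on
  one core; problem sizes in the tests are chosen at this scale.
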