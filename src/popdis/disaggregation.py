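"""Top-down population disaggregation methods.

Five methods redistribute source-zone (SZ) census counts to target zones
(TZ: urban pixels, buildings, or grid cells), all mass-preserving
(pycnophylactic) per SZ:

* binary dasymetric — allocation proportional to urban area or building
  size (footprint area x floors) inside each SZ;
* categorical dasymetric — adds land-use occupancy weights W_LU
  (residential fixed at 1; commercial/other calibrated by grid search);
* statistical — a random-forest model of population density at SZ level
  predicts a per-grid-cell weight layer W_P used as allocation weights;
* combined binary / categorical — dasymetric allocation modulated by W_P.

TZs split across SZ boundaries receive contributions from each side
(area-proportional shares).  A populated SZ whose weighted urban area is
zero falls back to uniform allocation over its full polygon, logged loudly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .geo_core import (
    OUTSIDE,
    InvalidInputError,
    OverlayTable,
    UrbanMask,
    ZoneSet,
    aggregate_estimate,
    proportional_overlay,
)

logger = logging.getLogger(__name__)

METHODS = ("DASY_BIN", "DASY_CAT", "STAT", "COMB_BIN", "COMB_CAT")


@dataclass
class OccupancyWeights:
    """Habitable share of floor area per land-use class (residential = 1)."""

    w_C: float = 0.4
    w_O: float = 0.3
    w_R: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.w_R, self.w_C, self.w_O):
            if not 0.0 <= w <= 1.0:
                raise InvalidInputError("occupancy weights must lie in [0, 1]")

    def factor(self, land_use: np.ndarray) -> np.ndarray:
        lut = {"R": self.w_R, "C": self.w_C, "O": self.w_O}
        return np.array([lut[l] for l in land_use], dtype=float)


@dataclass
class RFConfig:
    """Random-forest regression settings for the weight model."""

    n_trees: int = 500
    m_try: int = 3
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.m_try, self.min_leaf) < 1:
            raise InvalidInputError("RF config values must be positive integers")


@dataclass
class WeightLayer:
    """Non-negative per-grid-cell population-density weights."""

    grid: ZoneSet
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.grid):
            raise InvalidInputError("weight layer not aligned to grid")
        if (self.values < 0).any():
            raise InvalidInputError("weights must be non-negative")

    def at_points(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Weight of the grid cell containing each point (0 outside grid)."""
        spec = self.grid.grid
        if spec is None:
            raise InvalidInputError("weight layer grid lacks a GridSpec")
        x0, y0 = spec.origin
        cols = np.floor((np.asarray(xs) - x0) / spec.cell_size).astype(int)
        rows = np.floor((y0 - np.asarray(ys)) / spec.cell_size).astype(int)
        cell_ids = rows * spec.ncols + cols
        valid = (cols >= 0) & (cols < spec.ncols) & (rows >= 0) & (rows < spec.nrows)
        pos = pd.Series(
            np.arange(len(self.grid)), index=self.grid.unit_ids
        )
        out = np.zeros(len(cell_ids))
        hit = valid & pd.Index(cell_ids).isin(pos.index)
        out[hit] = self.values[pos.loc[cell_ids[hit]].to_numpy()]
        return out


@dataclass
class PopulationEstimate:
    """Per-TZ estimated population for one method run."""

    method: str
    tz_kind: str                 # "pixel" | "building" | "grid"
    df: pd.DataFrame             # tz_id, geometry, pop
    provenance: dict = field(default_factory=dict)
    fallback_szs: list = field(default_factory=list)
    #: population allocated per source zone (the pycnophylactic ledger);
    #: indexed by SZ unit_id, equals the census counts to float precision
    sz_allocated: pd.Series | None = None

    def total(self) -> float:
        return float(self.df["pop"].sum())


def _mask_features(mask: UrbanMask, dimension: str) -> pd.DataFrame:
    """TZ feature table with the habitable size for the requested dimension."""
    feats = mask.features()
    if mask.kind == "FOOTPRINT":
        size = feats["geometry"].map(lambda g: g.area).to_numpy(dtype=float)
        if dimension == "VOLUME":
            floors = mask.buildings["floors"].to_numpy(dtype=float)
            size = size * floors
        feats = feats.assign(size=size)
    elif dimension == "VOLUME":
        # raster VOLUME masks carry the floor factor in the cell values
        if mask.dimension != "VOLUME":
            raise InvalidInputError("VOLUME dimension requires a floor-weighted mask")
    return feats


def _allocate(
    feats: pd.DataFrame,
    sz: ZoneSet,
    factors: np.ndarray | None = None,
    method: str = "",
    overlay: OverlayTable | None = None,
    provenance: dict | None = None,
    tz_kind: str = "building",
) -> PopulationEstimate:
    """Generic pycnophylactic allocation: P_tz = a_tz * P_sz / sum_sz(a).

    ``a`` is the feature's apportioned size within the SZ times an optional
    per-feature factor (occupancy weight, statistical weight, or both).
    """
    if overlay is None:
        overlay = proportional_overlay(feats, sz)
    t = overlay.df
    t = t[t["unit_id"] != OUTSIDE]
    fpos = pd.Series(np.arange(len(feats)), index=feats["tz_id"])
    zpos = pd.Series(np.arange(len(sz)), index=sz.unit_ids)
    fi = fpos.loc[t["feature_id"]].to_numpy()
    zi = zpos.loc[t["unit_id"]].to_numpy()
    a = t["quantity"].to_numpy(dtype=float)
    if factors is not None:
        a = a * np.asarray(factors, dtype=float)[fi]

    denom = np.zeros(len(sz))
    np.add.at(denom, zi, a)
    pops = sz.populations
    fallback = np.nonzero((pops > 0) & (denom <= 0))[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom[zi] > 0, a / denom[zi], 0.0)
    contrib = share * pops[zi]

    tz_pop = np.zeros(len(feats))
    np.add.at(tz_pop, fi, contrib)
    allocated = np.zeros(len(sz))
    np.add.at(allocated, zi, contrib)
    allocated[fallback] = pops[fallback]
    out = pd.DataFrame(
        {"tz_id": feats["tz_id"].to_numpy(),
         "geometry": feats["geometry"].to_numpy(),
         "pop": tz_pop}
    )
    fb_ids = []
    if len(fallback):
        fb_ids = [sz.unit_ids[z] for z in fallback]
        logger.warning(
            "%s: %d populated SZ(s) with zero weighted urban area; "
            "falling back to uniform allocation over the SZ polygon: %s",
            method or "allocate", len(fallback), fb_ids,
        )
        fb = pd.DataFrame(
            {"tz_id": [f"FALLBACK_{u}" for u in fb_ids],
             "geometry": [sz.geometries[z] for z in fallback],
             "pop": [pops[z] for z in fallback]}
        )
        out = pd.concat([out, fb], ignore_index=True)
    return PopulationEstimate(
        method=method, tz_kind=tz_kind, df=out,
        provenance=provenance or {}, fallback_szs=fb_ids,
        sz_allocated=pd.Series(allocated, index=sz.unit_ids),
    )


def dasymetric_binary(
    sz: ZoneSet,
    mask: UrbanMask,
    dimension: str = "AREA",
    overlay: OverlayTable | None = None,
) -> PopulationEstimate:
    """Allocate SZ population across the urban mask by area/building size."""
    feats = _mask_features(mask, dimension)
    kind = "building" if mask.kind == "FOOTPRINT" else "pixel"
    return _allocate(
        feats, sz, method="DASY_BIN", overlay=overlay,
        provenance={"mask": mask.name, "dimension": dimension}, tz_kind=kind,
    )


def dasymetric_categorical(
    sz: ZoneSet,
    mask: UrbanMask,
    dimension: str = "AREA",
    w: OccupancyWeights | None = None,
    overlay: OverlayTable | None = None,
) -> PopulationEstimate:
    """Dasymetric allocation with land-use occupancy weights."""
    if not mask.has_land_use:
        raise InvalidInputError("categorical method requires a land-use mask")
    w = w or OccupancyWeights()
    feats = _mask_features(mask, dimension)
    factors = w.factor(feats["land_use"].to_numpy())
    return _allocate(
        feats, sz, factors=factors, method="DASY_CAT", overlay=overlay,
        provenance={"mask": mask.name, "dimension": dimension,
                    "w_C": w.w_C, "w_O": w.w_O},
        tz_kind="building",
    )


@dataclass
class WeightModelFit:
    """Fitted RF committee plus its internal (out-of-bag) fit report."""

    model: RandomForestRegressor
    columns: list[str]
    oob_r2: float          # %
    nrmse: float           # % of mean response
    config: RFConfig


def fit_weight_model(
    sz: ZoneSet,
    covariates: pd.DataFrame,
    rf: RFConfig | None = None,
) -> WeightModelFit:
    """Fit population density at SZ (pop / unit area) on the covariates.

    The out-of-bag R² (as %) and the normalized out-of-bag RMSE (% of the
    mean response) summarize the model, mirroring how weight-model quality
    is reported alongside the downstream validation.
    """
    rf = rf or RFConfig()
    if len(sz) <= rf.min_leaf:
        raise InvalidInputError("fewer SZ units than the terminal-node size")
    X = covariates.loc[pd.Index(sz.unit_ids)].to_numpy(dtype=float)
    y = sz.populations / sz.areas
    model = RandomForestRegressor(
        n_estimators=rf.n_trees,
        max_features=min(rf.m_try, X.shape[1]),
        min_samples_leaf=rf.min_leaf,
        oob_score=True,
        bootstrap=True,
        random_state=rf.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    oob = model.oob_prediction_
    oob = np.where(np.isnan(oob), float(np.mean(y)), oob)
    ss_res = float(np.sum((y - oob) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = (1.0 - ss_res / ss_tot) * 100.0 if ss_tot > 0 else np.nan
    nrmse = float(np.sqrt(ss_res / len(y)) / np.mean(y) * 100.0)
    return WeightModelFit(model, list(covariates.columns), r2, nrmse, rf)


def predict_weight_layer(fit: WeightModelFit, grid_covariates: pd.DataFrame,
                         grid: ZoneSet) -> WeightLayer:
    """Predict the per-cell density weight layer W_P; negatives clipped."""
    missing = [c for c in fit.columns if c not in grid_covariates.columns]
    if missing:
        raise InvalidInputError(f"grid covariates missing columns: {missing}")
    X = grid_covariates.loc[pd.Index(grid.unit_ids), fit.columns].to_numpy(dtype=float)
    pred = fit.model.predict(X)
    neg = int((pred < 0).sum())
    if neg:
        logger.info("clipped %d negative weight predictions to zero", neg)
    return WeightLayer(grid, np.clip(pred, 0.0, None))


def statistical_disaggregate(
    sz: ZoneSet,
    weights: WeightLayer,
    overlay: OverlayTable | None = None,
) -> PopulationEstimate:
    """Eq-style weight allocation onto the grid: P = W_P * P_SZ / sum W_P.

    Grid cells straddling SZ boundaries contribute area-proportional weight
    shares to each side.
    """
    grid = weights.grid
    feats = pd.DataFrame(
        {"tz_id": grid.unit_ids, "geometry": grid.geometries,
         "size": weights.values}
    )
    return _allocate(
        feats, sz, method="STAT", overlay=overlay,
        provenance={"tz": "grid"}, tz_kind="grid",
    )


def combined_disaggregate(
    sz: ZoneSet,
    mask: UrbanMask,
    dimension: str,
    weights: WeightLayer,
    w: OccupancyWeights | None = None,
    overlay: OverlayTable | None = None,
) -> PopulationEstimate:
    """Dasymetric allocation modulated by the statistical weight layer.

    Each TZ takes the W_P of the grid cell containing its centroid.  With
    occupancy weights the land-use factor multiplies in as well.
    """
    feats = _mask_features(mask, dimension)
    cents = shapely.centroid(np.asarray(feats["geometry"], dtype=object))
    wp = weights.at_points(shapely.get_x(cents), shapely.get_y(cents))
    factors = wp
    method = "COMB_BIN"
    prov = {"mask": mask.name, "dimension": dimension}
    if w is not None:
        if not mask.has_land_use:
            raise InvalidInputError("occupancy weights require a land-use mask")
        factors = wp * w.factor(feats["land_use"].to_numpy())
        method = "COMB_CAT"
        prov.update({"w_C": w.w_C, "w_O": w.w_O})
    kind = "building" if mask.kind == "FOOTPRINT" else "pixel"
    return _allocate(
        feats, sz, factors=factors, method=method, overlay=overlay,
        provenance=prov, tz_kind=kind,
    )


def estimate_to_grid(estimate: PopulationEstimate, grid: ZoneSet) -> PopulationEstimate:
    """Aggregate a pixel/building estimate onto the analysis grid."""
    per_unit, outside = aggregate_estimate(estimate.df, grid)
    df = pd.DataFrame(
        {"tz_id": grid.unit_ids, "geometry": grid.geometries,
         "pop": per_unit.to_numpy(dtype=float)}
    )
    prov = dict(estimate.provenance)
    prov["outside_grid"] = outside
    return PopulationEstimate(estimate.method, "grid", df, prov,
                              estimate.fallback_szs)


# ---------------------------------------------------------------------------
# occupancy-weight grid search
# ---------------------------------------------------------------------------

def search_occupancy_weights(
    sz: ZoneSet,
    masks: dict[str, UrbanMask],
    vz_levels: dict[str, ZoneSet],
    grid_step: float = 0.1,
) -> tuple[OccupancyWeights, pd.DataFrame]:
    """Grid-search (w_C, w_O) over {0, step, ..., 1}^2 with w_R = 1.

    For every pair and each mask dimension (AREA and VOLUME), the
    categorical estimate is scored with normalized RMSE and RTAE at L1 and
    L0 plus OE and UE at L0.  The pair minimizing the rank sum across all
    recorded metric columns wins; exact ties break toward higher occupancy.
    Returns the winner and the full search table.
    """
    from .validation import build_series, compute_metrics

    nsteps = round(1.0 / grid_step)
    if abs(nsteps * grid_step - 1.0) > 1e-9:
        raise InvalidInputError("grid_step must divide 1 evenly")
    levels = np.round(np.linspace(0.0, 1.0, nsteps + 1), 10)

    # precompute per mask: SZ overlay quantities and VZ aggregation shares
    pre = {}
    for mname, mask in masks.items():
        dim = mask.dimension
        feats = _mask_features(mask, dim)
        lu = feats["land_use"].to_numpy()
        ov = proportional_overlay(feats, sz)
        vz_shares = {}
        for lname, vz in vz_levels.items():
            t = proportional_overlay(feats, vz).df
            fpos = pd.Series(np.arange(len(feats)), index=feats["tz_id"])
            vz_shares[lname] = (
                fpos.loc[t["feature_id"]].to_numpy(),
                t["unit_id"].to_numpy(),
                t["fraction"].to_numpy(dtype=float),
            )
        pre[mname] = (feats, lu, ov, vz_shares)

    rows = []
    for w_C, w_O in itertools.product(levels, levels):
        w = OccupancyWeights(w_C=float(w_C), w_O=float(w_O))
        for mname, (feats, lu, ov, vz_shares) in pre.items():
            est = _allocate(
                feats, sz, factors=w.factor(lu), method="DASY_CAT", overlay=ov
            )
            tz_pop = est.df["pop"].to_numpy()[: len(feats)]
            rec = {"w_C": float(w_C), "w_O": float(w_O), "mask": mname}
            for lname, vz in vz_levels.items():
                fi, uid, frac = vz_shares[lname]
                agg = pd.Series(tz_pop[fi] * frac).groupby(uid).sum()
                inside = agg[agg.index != OUTSIDE]
                series = build_series(vz, None, per_unit=inside)
                rep = compute_metrics(series)
                rec[f"nrmse_{lname}"] = rep.nrmse
                rec[f"rtae_{lname}"] = rep.rtae
                if lname == "L0":
                    rec["oe_L0"] = rep.oe
                    rec["ue_L0"] = rep.ue
            rows.append(rec)
    table = pd.DataFrame(rows)

    metric_cols = [c for c in table.columns if c.startswith(("nrmse", "rtae", "oe", "ue"))]
    # one ranked column per (mask, metric): 12 columns for two masks
    per_pair = table.pivot_table(
        index=["w_C", "w_O"], columns="mask", values=metric_cols, sort=True
    )
    ranks = np.column_stack([rankdata(per_pair[c]) for c in per_pair.columns])
    score = pd.Series(ranks.sum(axis=1), index=per_pair.index)
    best_score = score.min()
    tied = score[score <= best_score + 1e-9]
    if len(tied) > 1:
        logger.warning("occupancy search: %d tied pairs; choosing highest occupancy",
                       len(tied))
    w_C, w_O = sorted(tied.index.tolist())[-1]
    table = table.merge(
        score.rename("rank_sum"), left_on=["w_C", "w_O"], right_index=True
    )
    return OccupancyWeights(w_C=float(w_C), w_O=float(w_O)), table
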