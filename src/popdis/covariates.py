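"""Geospatial covariates for source zones and grid cells.

Covariate families
------------------
* densities (``den_*``): apportioned feature area / floor area / length /
  point count divided by unit area (proportional-area overlay);
* nearest distances (``dst_*``): the target layer is rasterized, a Euclidean
  distance transform is computed, and distances are averaged over the cells
  whose centres fall in each unit;
* landscape metrics on the binary urban mask (``MS, SI, P, C, EMS, DO, DI,
  ENND, AWSDn``), all normalized to be dimensionless;
* terrain statistics (``m_dem, sd_dem, m_slo, sd_slo``) by cell-centre
  membership.

The experiment design draws four nested covariate cases per urban mask,
from most to least data:  A = everything; B = A minus land-use and
establishment covariates; C = urban mask + spatial metrics + road network;
D = urban mask + spatial metrics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree

from .geo_core import (
    InvalidInputError,
    UrbanMask,
    ZoneSet,
    proportional_overlay,
    terrain_cell_membership,
)
from .raster import Raster, paint_binary

logger = logging.getLogger(__name__)

SPATIAL_METRICS = ("MS", "SI", "P", "C", "EMS", "DO", "DI", "ENND", "AWSDn")

CASES = ("A", "B", "C", "D")

_DEFAULT_R_THRESHOLD = 0.85


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def density_covariate(
    layer,
    zones: ZoneSet,
    volume: bool = False,
) -> pd.Series:
    """Per-unit density of a layer (area, floor area, length or count / m^2).

    ``layer`` may be an :class:`UrbanMask`, or a DataFrame of polygon, line
    or point geometries.  Quantities are apportioned by proportional area
    (polygons, raster cells), clipped length (lines) or containment (points).
    """
    if (zones.areas <= 0).any():
        raise InvalidInputError("zones with zero area")
    if isinstance(layer, UrbanMask):
        feats = layer.features()
        if volume and layer.dimension != "VOLUME":
            raise InvalidInputError("volume density requires a VOLUME mask")
        if not volume and layer.kind == "FOOTPRINT":
            feats = feats.assign(size=feats["geometry"].map(lambda g: g.area))
        table = proportional_overlay(feats, zones)
        per_unit = table.per_unit()
    else:
        df = layer
        if len(df) == 0:
            return pd.Series(0.0, index=zones.unit_ids, name="density")
        geoms = np.asarray(df["geometry"], dtype=object)
        gtypes = shapely.get_type_id(geoms)
        if np.all(np.isin(gtypes, (0, 4))):        # points
            tree = shapely.STRtree(geoms)
            counts = pd.Series(0.0, index=range(len(zones)))
            for zidx, zg in enumerate(zones.geometries):
                counts[zidx] = len(tree.query(zg, predicate="covers"))
            per_unit = pd.Series(counts.to_numpy(), index=zones.unit_ids)
        elif np.all(np.isin(gtypes, (1, 5))):      # lines: clipped length
            tree = shapely.STRtree(geoms)
            lengths = np.zeros(len(zones))
            for zidx, zg in enumerate(zones.geometries):
                hit = tree.query(zg, predicate="intersects")
                if len(hit):
                    lengths[zidx] = shapely.length(
                        shapely.intersection(geoms[hit], zg)
                    ).sum()
            per_unit = pd.Series(lengths, index=zones.unit_ids)
        else:                                       # polygons
            feats = pd.DataFrame(
                {"tz_id": np.arange(len(df)), "geometry": geoms,
                 "size": shapely.area(geoms)}
            )
            table = proportional_overlay(feats, zones)
            per_unit = table.per_unit()
    per_unit = per_unit.reindex(zones.unit_ids, fill_value=0.0)
    return per_unit / pd.Series(zones.areas, index=zones.unit_ids)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _target_cells(layer, extent, resolution: float) -> np.ndarray:
    """Boolean occupancy grid of the target layer at the given resolution."""
    xmin, ymin, xmax, ymax = extent
    nc = int(np.ceil((xmax - xmin) / resolution))
    nr = int(np.ceil((ymax - ymin) / resolution))
    occ = np.zeros((nr, nc), dtype=bool)
    if isinstance(layer, Raster):
        if abs(layer.cell_size - resolution) > 1e-9:
            raise InvalidInputError("raster target must match the stated resolution")
        vals = np.asarray(layer.values, dtype=float)
        sub = (vals > 0) & (vals != layer.nodata)
        occ[: sub.shape[0], : sub.shape[1]] = sub[:nr, :nc]
        return occ
    if isinstance(layer, UrbanMask):
        if layer.kind == "RASTER":
            return _target_cells(layer.raster, extent, resolution)
        layer = layer.buildings
    df = layer
    if len(df) == 0:
        return occ
    geoms = np.asarray(df["geometry"], dtype=object)
    gtypes = shapely.get_type_id(geoms)
    if np.all(np.isin(gtypes, (0, 4))):
        xs = shapely.get_x(geoms)
        ys = shapely.get_y(geoms)
        cols = np.clip(((xs - xmin) // resolution).astype(int), 0, nc - 1)
        rows = np.clip(((ymax - ys) // resolution).astype(int), 0, nr - 1)
        occ[rows, cols] = True
        return occ
    if np.all(np.isin(gtypes, (1, 5))):
        # sample points along each line at half-resolution spacing
        for g in geoms:
            npts = max(2, int(np.ceil(g.length / (resolution / 2))) + 1)
            pts = shapely.line_interpolate_point(
                g, np.linspace(0.0, g.length, npts)
            )
            xs = shapely.get_x(pts)
            ys = shapely.get_y(pts)
            cols = np.clip(((xs - xmin) // resolution).astype(int), 0, nc - 1)
            rows = np.clip(((ymax - ys) // resolution).astype(int), 0, nr - 1)
            occ[rows, cols] = True
        return occ
    occ |= paint_binary(geoms, extent, base=resolution)
    # tiny polygons can miss every cell centre; mark their centroid cells
    cents = shapely.centroid(geoms)
    xs = shapely.get_x(cents)
    ys = shapely.get_y(cents)
    cols = np.clip(((xs - xmin) // resolution).astype(int), 0, nc - 1)
    rows = np.clip(((ymax - ys) // resolution).astype(int), 0, nr - 1)
    occ[rows, cols] = True
    return occ


def distance_covariate(
    target,
    zones: ZoneSet,
    resolution: float,
    cap: float,
    extent: tuple[float, float, float, float] | None = None,
    membership: np.ndarray | None = None,
) -> pd.Series:
    """Mean Euclidean distance (m) from each cell in a unit to the target.

    The target is rasterized at ``resolution``; a distance transform gives
    per-cell distances; unit means are taken over cells whose centres lie in
    the unit.  An empty target yields the cap for every unit.
    """
    if resolution <= 0:
        raise InvalidInputError("resolution must be positive")
    if extent is None:
        b = shapely.bounds(zones.geometries)
        extent = (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())
    occ = _target_cells(target, extent, resolution)
    if not occ.any():
        return pd.Series(cap, index=zones.unit_ids, name="distance")
    dist = ndimage.distance_transform_edt(~occ) * resolution
    rast = Raster(dist, (extent[0], extent[3]), resolution)
    return zonal_stat(rast, zones, membership=membership)["mean"]


def zonal_stat(
    raster: Raster,
    zones: ZoneSet,
    membership: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and population-sd of raster values per unit (cell-centre rule).

    A unit containing no cell centre receives the value of the nearest cell
    (with a warning), so covariate tables never carry missing values.
    """
    if membership is None:
        membership = terrain_cell_membership(raster, zones)
    vals = np.asarray(raster.values, dtype=float).ravel()
    mem = membership.ravel()
    ok = mem >= 0
    n = np.bincount(mem[ok], minlength=len(zones)).astype(float)
    s = np.bincount(mem[ok], weights=vals[ok], minlength=len(zones))
    s2 = np.bincount(mem[ok], weights=vals[ok] ** 2, minlength=len(zones))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = np.maximum(s2 / n - mean**2, 0.0)
    empty = n == 0
    if empty.any():
        logger.warning("%d unit(s) contain no cell centres; using nearest cell", empty.sum())
        X, Y = raster.cell_centers()
        tree = cKDTree(np.column_stack([X.ravel(), Y.ravel()]))
        cents = shapely.centroid(zones.geometries[empty])
        _, idx = tree.query(np.column_stack([shapely.get_x(cents), shapely.get_y(cents)]))
        mean[empty] = vals[idx]
        var[empty] = 0.0
    return pd.DataFrame(
        {"mean": mean, "sd": np.sqrt(var)}, index=pd.Index(zones.unit_ids, name="unit_id")
    )


def terrain_stats(
    dem: Raster,
    slope: Raster,
    zones: ZoneSet,
    membership: np.ndarray | None = None,
) -> pd.DataFrame:
    """m_dem, sd_dem, m_slo, sd_slo per unit (population-sd, n denominator)."""
    d = zonal_stat(dem, zones, membership=membership)
    s = zonal_stat(slope, zones, membership=membership)
    return pd.DataFrame(
        {"m_dem": d["mean"], "sd_dem": d["sd"], "m_slo": s["mean"], "sd_slo": s["sd"]}
    )


# ---------------------------------------------------------------------------
# landscape metrics
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def _patch_stats(urban: np.ndarray, cell: float):
    """Label urban patches (8-connectivity) and return per-patch arrays."""
    lab, npatch = ndimage.label(urban, structure=_EIGHT)
    if npatch == 0:
        return lab, npatch, None
    idx = np.arange(1, npatch + 1)
    counts = ndimage.sum_labels(np.ones_like(lab), lab, idx)
    areas = counts * cell * cell
    # perimeter: exposed cell edges
    padded = np.pad(lab, 1)
    perims = np.zeros(npatch)
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = np.roll(padded, shift, axis=(0, 1))[1:-1, 1:-1]
        exposed = urban & (neigh != lab)
        if exposed.any():
            perims += ndimage.sum_labels(exposed.astype(float), lab, idx)
    perims *= cell
    cents = np.array(ndimage.center_of_mass(urban, lab, idx), dtype=float)
    cents = cents.reshape(npatch, 2) * cell  # (row, col) scaled to metres
    return lab, npatch, (areas, perims, cents)


def landscape_metrics_window(
    urban: np.ndarray, cell: float, unit_area: float
) -> dict[str, float]:
    """The nine metrics for one unit's clipped binary mask window."""
    out = {m: 0.0 for m in SPATIAL_METRICS}
    lab, npatch, stats = _patch_stats(np.asarray(urban, dtype=bool), cell)
    if npatch == 0:
        out["ENND"] = 1.0
        return out
    areas, perims, cents = stats
    radius = np.sqrt(unit_area / np.pi)
    urban_area = areas.sum()
    out["MS"] = float(areas.mean() / unit_area)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["SI"] = float(np.mean(perims / (2.0 * np.sqrt(np.pi * areas))))
        out["C"] = float(np.mean(np.where(perims > 0, 4 * np.pi * areas / perims**2, 1.0)))
    out["EMS"] = float(np.sum(areas**2) / unit_area**2)
    out["DO"] = float(npatch / (unit_area / 1e6))
    # porosity: share of the urban convex envelope left unbuilt
    rows, cols = np.nonzero(lab)
    pts = shapely.points(cols * cell, -rows * cell)
    hull = shapely.convex_hull(shapely.union_all(pts))
    hull_area = max(hull.area, urban_area)
    out["P"] = float(1.0 - urban_area / hull_area) if hull_area > 0 else 0.0
    joint = cents.mean(axis=0)
    out["DI"] = float(np.mean(np.linalg.norm(cents - joint, axis=1)) / radius)
    w = areas / urban_area
    cw = (cents * w[:, None]).sum(axis=0)
    out["AWSDn"] = float(np.sqrt((w * ((cents - cw) ** 2).sum(axis=1)).sum()) / radius)
    if npatch == 1:
        out["ENND"] = 1.0
    else:
        cell_pts = np.column_stack([rows, cols]).astype(float) * cell
        labels = lab[rows, cols]
        tree = cKDTree(cell_pts)
        nnd = np.full(npatch, np.inf)
        k = min(len(cell_pts), 16)
        dists, neigh = tree.query(cell_pts, k=k)
        for i in range(1, npatch + 1):
            sel = labels == i
            other = labels[neigh[sel]] != i
            found = other.any(axis=1)
            if found.any():
                d = np.where(other[found], dists[sel][found], np.inf).min(axis=1)
                nnd[i - 1] = d.min()
        # fall back to brute force for patches whose k-NN were all same-patch
        missing = ~np.isfinite(nnd)
        if missing.any():
            for i in np.nonzero(missing)[0] + 1:
                own = cell_pts[labels == i]
                rest = cell_pts[labels != i]
                sub = cKDTree(rest)
                nnd[i - 1] = sub.query(own)[0].min()
        edge = np.maximum(nnd - cell, 0.0)   # centre-to-centre -> edge-to-edge
        out["ENND"] = float(np.mean(edge) / radius)
    return out


def landscape_metrics(
    mask: UrbanMask | Raster,
    zones: ZoneSet,
    membership: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-unit landscape metrics of a binary mask raster."""
    rast = mask.raster if isinstance(mask, UrbanMask) else mask
    if rast is None:
        raise InvalidInputError("landscape metrics require a raster mask")
    urban = np.asarray(rast.values) > 0
    if membership is None:
        membership = terrain_cell_membership(rast, zones)
    rows = []
    nr, nc = urban.shape
    for zidx in range(len(zones)):
        sel = membership == zidx
        if not sel.any():
            m = {m_: 0.0 for m_ in SPATIAL_METRICS}
            m["ENND"] = 1.0
        else:
            rr, cc = np.nonzero(sel)
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            window = urban[r0:r1, c0:c1] & sel[r0:r1, c0:c1]
            m = landscape_metrics_window(window, rast.cell_size, float(zones.areas[zidx]))
        rows.append(m)
    return pd.DataFrame(rows, index=pd.Index(zones.unit_ids, name="unit_id"))


# ---------------------------------------------------------------------------
# assembly and pruning
# ---------------------------------------------------------------------------

def case_columns(case: str, mask_name: str) -> list[str]:
    """Ordered covariate subset for one (case, mask) experiment."""
    if case not in CASES:
        raise InvalidInputError(f"unknown covariate case {case!r}")
    vhr = mask_name.startswith(("VHR", "3D")) if mask_name else False
    three_d = mask_name.startswith("3D") if mask_name else False
    cols = list(SPATIAL_METRICS) + ["den_urb", "dst_urb"]
    if three_d:
        cols.append("den_bs")
    if case in ("A", "B", "C"):
        cols += ["den_roa", "dst_roa", "den_int", "dst_int"]
    if case in ("A", "B"):
        cols += ["m_dem", "sd_dem", "m_slo", "sd_slo", "den_veg", "dst_veg"]
    if case == "A":
        if vhr:
            cols += ["den_res_b", "dst_res_b", "den_com_b", "dst_com_b",
                     "den_oth_b", "dst_oth_b"]
            if three_d:
                cols += ["den_res_bs", "den_com_bs", "den_oth_bs"]
        else:
            cols += ["den_res", "dst_res", "den_com", "dst_com", "den_oth", "dst_oth"]
        cols += ["den_est", "dst_est"]
    return cols


def assemble(case: str, mask_name: str, full_table: pd.DataFrame) -> pd.DataFrame:
    """Select the covariate subset an experiment draws from the full table."""
    cols = case_columns(case, mask_name)
    missing = [c for c in cols if c not in full_table.columns]
    if missing:
        raise InvalidInputError(f"missing required covariate layer(s): {missing}")
    return full_table[cols].copy()


class CovariateBuilder:
    """Computes and caches full covariate tables for a city bundle.

    One builder serves every experiment on a bundle: ancillary covariates
    (roads, terrain, vegetation, land use, establishments) are shared across
    masks and computed once per unit set; mask-dependent covariates (spatial
    metrics, den_urb/dst_urb, den_bs) are cached per mask family.
    """

    #: analysis resolution for ancillary distance covariates, metres
    ANCILLARY_RES = 10.0

    def __init__(self, city, cap: float | None = None):
        self.city = city
        self.extent = city.extent
        xmin, ymin, xmax, ymax = self.extent
        self.cap = cap if cap is not None else float(np.hypot(xmax - xmin, ymax - ymin))
        self._mem: dict = {}
        self._ancillary: dict = {}
        self._mask_cols: dict = {}
        self._vhr_raster: Raster | None = None

    # -- caches -----------------------------------------------------------
    def _membership(self, zones: ZoneSet, raster: Raster) -> np.ndarray:
        key = (zones.level, raster.cell_size, raster.shape)
        if key not in self._mem:
            self._mem[key] = terrain_cell_membership(raster, zones)
        return self._mem[key]

    def _grid_raster(self, resolution: float) -> Raster:
        xmin, ymin, xmax, ymax = self.extent
        nc = int(np.ceil((xmax - xmin) / resolution))
        nr = int(np.ceil((ymax - ymin) / resolution))
        return Raster(np.zeros((nr, nc)), (xmin, ymax), resolution)

    def _dst(self, target, zones: ZoneSet, resolution: float) -> pd.Series:
        mem = self._membership(zones, self._grid_raster(resolution))
        return distance_covariate(
            target, zones, resolution, self.cap, extent=self.extent, membership=mem
        )

    def vhr_raster(self) -> Raster:
        """Binary rasterization of building footprints at the HR cell size."""
        if self._vhr_raster is None:
            from .raster import coverage_raster

            cov = coverage_raster(
                np.asarray(self.city.buildings["geometry"], dtype=object),
                self.extent,
                self.city.config.hr_cell,
            )
            self._vhr_raster = Raster(
                (cov.values >= 0.5).astype(np.uint8), cov.origin, cov.cell_size
            )
        return self._vhr_raster

    def _mask_raster(self, mask_name: str) -> Raster:
        if mask_name == "MR":
            return self.city.mask_mr
        if mask_name == "HR":
            return self.city.mask_hr
        return self.vhr_raster()

    # -- covariate blocks -------------------------------------------------
    def ancillary(self, zones: ZoneSet) -> pd.DataFrame:
        key = zones.level
        if key in self._ancillary:
            return self._ancillary[key]
        city = self.city
        res = self.ANCILLARY_RES
        idx = pd.Index(zones.unit_ids, name="unit_id")
        out = pd.DataFrame(index=idx)
        out["den_roa"] = density_covariate(city.roads, zones)
        out["dst_roa"] = self._dst(city.roads, zones, res)
        inter = pd.DataFrame({"geometry": city.road_intersections()})
        out["den_int"] = density_covariate(inter, zones)
        out["dst_int"] = self._dst(inter, zones, res)
        dem_mem = self._membership(zones, city.dem)
        out = out.join(terrain_stats(city.dem, city.slope, zones, membership=dem_mem))
        out["den_veg"] = density_covariate(city.vegetation, zones)
        out["dst_veg"] = self._dst(city.vegetation, zones, res)
        # land use: zone polygons for the coarse masks, buildings for VHR
        lu_zones = city.landuse_zones()
        b = city.buildings
        for lu, tag in (("R", "res"), ("C", "com"), ("O", "oth")):
            zsub = lu_zones[lu_zones["land_use"] == lu]
            out[f"den_{tag}"] = density_covariate(zsub, zones)
            out[f"dst_{tag}"] = self._dst(zsub, zones, res)
            bsub = b[b["land_use"] == lu]
            out[f"den_{tag}_b"] = density_covariate(bsub[["geometry"]], zones)
            out[f"dst_{tag}_b"] = self._dst(bsub[["geometry"]], zones, res)
            feats = pd.DataFrame(
                {"tz_id": bsub["building_id"].to_numpy(),
                 "geometry": bsub["geometry"].to_numpy(),
                 "size": (bsub["area"] * bsub["floors"]).to_numpy(dtype=float)}
            )
            per_unit = (
                proportional_overlay(feats, zones).per_unit()
                .reindex(zones.unit_ids, fill_value=0.0)
            )
            out[f"den_{tag}_bs"] = per_unit.to_numpy() / zones.areas
        out["den_est"] = density_covariate(city.establishments, zones)
        out["dst_est"] = self._dst(city.establishments, zones, res)
        self._ancillary[key] = out
        return out

    def mask_block(self, mask_name: str, zones: ZoneSet) -> pd.DataFrame:
        family = "VHR" if mask_name.startswith(("VHR", "3D")) else mask_name
        key = (family, zones.level, mask_name.startswith("3D"))
        if key in self._mask_cols:
            return self._mask_cols[key]
        city = self.city
        idx = pd.Index(zones.unit_ids, name="unit_id")
        out = pd.DataFrame(index=idx)
        rast = self._mask_raster(mask_name)
        mem = self._membership(zones, rast)
        if family == "VHR":
            mask = UrbanMask("FOOTPRINT", "AREA", buildings=city.buildings, name="VHR")
            out["den_urb"] = density_covariate(mask, zones)
        else:
            mask = UrbanMask("RASTER", "AREA", raster=rast, name=mask_name)
            out["den_urb"] = density_covariate(mask, zones)
        out["dst_urb"] = distance_covariate(
            rast, zones, rast.cell_size, self.cap, extent=self.extent, membership=mem
        )
        out = out.join(landscape_metrics(rast, zones, membership=mem))
        if mask_name.startswith("3D"):
            vol = UrbanMask(
                "FOOTPRINT", "VOLUME", buildings=city.buildings, name="3D_VHR"
            )
            out["den_bs"] = density_covariate(vol, zones, volume=True)
        self._mask_cols[key] = out
        return out

    def full_table(self, mask_name: str, zones: ZoneSet) -> pd.DataFrame:
        """All case-A covariates for one mask and unit set."""
        table = self.mask_block(mask_name, zones).join(self.ancillary(zones))
        return table

    def table(self, case: str, mask_name: str, zones: ZoneSet) -> pd.DataFrame:
        return assemble(case, mask_name, self.full_table(mask_name, zones))


def prune(
    table: pd.DataFrame,
    dependent: pd.Series,
    unit_area: pd.Series,
    r_threshold: float = _DEFAULT_R_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop near-duplicate covariates and unit-size surrogates.

    Among any covariate pair with |Pearson r| > threshold the one with the
    smaller |r| against the dependent is dropped; covariates with
    |r| > threshold against unit area are dropped too.  Returns the pruned
    table and a report of (column, reason) rows.  Idempotent.
    """
    dep = np.asarray(dependent, dtype=float)
    area = np.asarray(unit_area, dtype=float)
    dropped: list[tuple[str, str]] = []
    cols = list(table.columns)

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    keep: list[str] = []
    variances = {c: float(np.var(table[c].to_numpy(dtype=float))) for c in cols}
    r_dep = {c: abs(_corr(table[c].to_numpy(dtype=float), dep)) for c in cols}
    for c in cols:
        if variances[c] == 0:
            dropped.append((c, "zero variance"))
    live = [c for c in cols if variances[c] > 0]
    for c in live:
        if abs(_corr(table[c].to_numpy(dtype=float), area)) > r_threshold:
            dropped.append((c, "correlated with unit size"))
    live = [c for c in live if all(d[0] != c for d in dropped)]
    # greedy: strongest predictors claim their cluster
    for c in sorted(live, key=lambda c: (-r_dep[c], live.index(c))):
        x = table[c].to_numpy(dtype=float)
        clash = next(
            (k for k in keep if abs(_corr(x, table[k].to_numpy(dtype=float))) > r_threshold),
            None,
        )
        if clash is None:
            keep.append(c)
        else:
            dropped.append((c, f"collinear with {clash}"))
    keep_ordered = [c for c in cols if c in keep]
    report = pd.DataFrame(dropped, columns=["column", "reason"])
    return table[keep_ordered].copy(), report
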