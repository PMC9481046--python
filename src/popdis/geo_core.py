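"""Spatial data model and proportional-area overlay machinery.

The package works entirely in a planar metric coordinate frame (a local
Cartesian frame for synthetic cities, a projected municipal frame for real
data).  Census geography is a three-level nesting of *sectors* (L2),
*sections* (L1) and *urban blocks* (L0); a regular analysis grid (default
100 m) serves as target zones for the gridded population products.

Two overlay conventions coexist, both used throughout the pipeline:

* **proportional area** — a feature (building, urban pixel, grid cell) that
  straddles several spatial units is split, and each unit receives the
  intersection-area fraction of the feature's quantity;
* **cell-centre membership** — terrain statistics assign each raster cell to
  the single unit containing its centre, with no splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree
from shapely.geometry import box

from .raster import Raster

logger = logging.getLogger(__name__)

#: sentinel unit id for feature mass falling outside every zone
OUTSIDE = "OUTSIDE"

LEVELS = ("L0", "L1", "L2", "GRID")
LAND_USES = ("R", "C", "O")


class InvalidInputError(ValueError):
    """Raised when inputs violate the documented preconditions."""


@dataclass
class GridSpec:
    """Regular square analysis grid, row-major from the north-west corner."""

    origin: tuple[float, float]   # top-left corner (x, y)
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.nrows <= 0 or self.ncols <= 0:
            raise InvalidInputError("grid spec requires positive cell size and counts")

    def cell_polygon(self, row: int, col: int):
        x0, y0 = self.origin
        return box(
            x0 + col * self.cell_size,
            y0 - (row + 1) * self.cell_size,
            x0 + (col + 1) * self.cell_size,
            y0 - row * self.cell_size,
        )

    def cell_polygons(self) -> np.ndarray:
        """All cell polygons, row-major (row 0 = northernmost)."""
        x0, y0 = self.origin
        rows, cols = np.divmod(np.arange(self.nrows * self.ncols), self.ncols)
        xmin = x0 + cols * self.cell_size
        ymax = y0 - rows * self.cell_size
        return shapely.box(xmin, ymax - self.cell_size, xmin + self.cell_size, ymax)


class ZoneSet:
    """A set of polygonal spatial units at one census level.

    Backed by a DataFrame with columns ``unit_id``, ``geometry``, ``area``,
    ``pop`` and optionally ``parent_id`` plus any extra attributes.
    """

    def __init__(
        self,
        level: str,
        df: pd.DataFrame,
        crs: str = "local",
        grid: GridSpec | None = None,
        validate: bool = True,
    ):
        if level not in LEVELS:
            raise InvalidInputError(f"unknown level {level!r}")
        df = df.reset_index(drop=True).copy()
        if "area" not in df.columns:
            df["area"] = shapely.area(np.asarray(df["geometry"], dtype=object))
        if "pop" not in df.columns:
            df["pop"] = 0.0
        if validate:
            if df["unit_id"].duplicated().any():
                raise InvalidInputError("unit_ids must be unique")
            if (df["area"] <= 0).any():
                raise InvalidInputError("unit areas must be strictly positive")
            if (df["pop"] < 0).any():
                raise InvalidInputError("populations must be non-negative")
        self.level = level
        self.df = df
        self.crs = crs
        self.grid = grid

    def __len__(self) -> int:
        return len(self.df)

    @property
    def unit_ids(self) -> np.ndarray:
        return self.df["unit_id"].to_numpy()

    @property
    def geometries(self) -> np.ndarray:
        return np.asarray(self.df["geometry"], dtype=object)

    @property
    def populations(self) -> np.ndarray:
        return self.df["pop"].to_numpy(dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return self.df["area"].to_numpy(dtype=float)

    def total_population(self) -> float:
        return float(self.df["pop"].sum())

    def check_nesting(self, parents: "ZoneSet", atol: float = 0.0) -> None:
        """Verify that child populations sum to each parent's count."""
        sums = self.df.groupby("parent_id")["pop"].sum()
        for _, row in parents.df.iterrows():
            child = float(sums.get(row["unit_id"], 0.0))
            if abs(child - row["pop"]) > atol:
                raise InvalidInputError(
                    f"nesting violated at {row['unit_id']}: "
                    f"children sum {child}, parent {row['pop']}"
                )


@dataclass
class UrbanMask:
    """Raster or footprint layer delimiting where population may live.

    ``dimension`` AREA uses plain built-up area; VOLUME uses building size
    (footprint area x floors, or floor-weighted raster cell values).
    """

    kind: str                       # "RASTER" | "FOOTPRINT"
    dimension: str = "AREA"         # "AREA" | "VOLUME"
    raster: Raster | None = None
    buildings: pd.DataFrame | None = None
    name: str = ""
    crs: str = "local"

    def __post_init__(self) -> None:
        if self.kind not in ("RASTER", "FOOTPRINT"):
            raise InvalidInputError(f"unknown mask kind {self.kind!r}")
        if self.dimension not in ("AREA", "VOLUME"):
            raise InvalidInputError(f"unknown dimension {self.dimension!r}")
        if self.kind == "RASTER" and self.raster is None:
            raise InvalidInputError("RASTER mask requires a raster")
        if self.kind == "FOOTPRINT":
            if self.buildings is None:
                raise InvalidInputError("FOOTPRINT mask requires buildings")
            b = self.buildings
            if "area" not in b.columns:
                b = b.copy()
                b["area"] = shapely.area(np.asarray(b["geometry"], dtype=object))
                self.buildings = b
            if self.dimension == "VOLUME" and "floors" not in b.columns:
                raise InvalidInputError("VOLUME dimension requires floors")
            if "land_use" in b.columns:
                bad = set(b["land_use"].dropna()) - set(LAND_USES)
                if bad:
                    raise InvalidInputError(f"unknown land-use labels: {sorted(bad)}")

    @property
    def has_land_use(self) -> bool:
        return self.kind == "FOOTPRINT" and "land_use" in self.buildings.columns

    def features(self) -> pd.DataFrame:
        """Urban features as (tz_id, geometry, size[, land_use]).

        For rasters, urban cells (value > 0) become square polygons with size
        value x cell area (binary masks: size = cell area; floor-weighted
        masks carry the volume factor in the cell value).  For footprints,
        size is footprint area (AREA) or total floor area (VOLUME).
        """
        if self.kind == "FOOTPRINT":
            b = self.buildings
            size = b["area"].to_numpy(dtype=float)
            if self.dimension == "VOLUME":
                size = size * b["floors"].to_numpy(dtype=float)
            out = pd.DataFrame(
                {
                    "tz_id": b["building_id"].to_numpy(),
                    "geometry": b["geometry"].to_numpy(),
                    "size": size,
                }
            )
            if "land_use" in b.columns:
                out["land_use"] = b["land_use"].to_numpy()
            return out
        r = self.raster
        vals = np.asarray(r.values, dtype=float)
        rows, cols = np.nonzero((vals > 0) & (vals != r.nodata))
        x0, y0 = r.origin
        cs = r.cell_size
        xmin = x0 + cols * cs
        ymax = y0 - rows * cs
        geoms = shapely.box(xmin, ymax - cs, xmin + cs, ymax)
        size = vals[rows, cols] * cs * cs
        return pd.DataFrame(
            {"tz_id": rows * r.shape[1] + cols, "geometry": geoms, "size": size}
        )


@dataclass
class OverlayTable:
    """Long-form apportionment of features onto spatial units."""

    df: pd.DataFrame  # feature_id, unit_id, fraction, quantity

    def per_unit(self) -> pd.Series:
        inside = self.df[self.df["unit_id"] != OUTSIDE]
        return inside.groupby("unit_id", sort=False)["quantity"].sum()

    def outside(self) -> float:
        return float(self.df.loc[self.df["unit_id"] == OUTSIDE, "quantity"].sum())


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    clip=None,
) -> ZoneSet:
    """Tile an extent with square cells; edge cells extend past the extent.

    Cells intersecting the optional clip polygon are kept whole; cells wholly
    outside it are dropped.  Ids are row-major integers from the north-west.
    """
    xmin, ymin, xmax, ymax = extent
    if cell_size <= 0:
        raise InvalidInputError("cell_size must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise InvalidInputError("degenerate extent")
    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    spec = GridSpec((xmin, ymin + nrows * cell_size), cell_size, nrows, ncols)
    geoms = spec.cell_polygons()
    ids = np.arange(nrows * ncols)
    if clip is not None:
        keep = shapely.intersects(geoms, clip)
        geoms, ids = geoms[keep], ids[keep]
    df = pd.DataFrame(
        {"unit_id": ids, "geometry": geoms, "area": cell_size**2, "pop": 0.0}
    )
    return ZoneSet("GRID", df, grid=spec)


def proportional_overlay(
    features: pd.DataFrame,
    zones: ZoneSet,
    quantity_col: str = "size",
    id_col: str = "tz_id",
    crs: str = "local",
) -> OverlayTable:
    """Apportion feature quantities to zones by intersection-area fraction.

    Features wholly inside one zone get fraction 1 (cheap bulk containment
    test); only boundary-straddling features pay for polygon intersection.
    Residual mass outside every zone is booked under the ``OUTSIDE`` id so
    totals are always conserved.
    """
    if crs != zones.crs:
        raise InvalidInputError(f"coordinate reference mismatch: {crs} vs {zones.crs}")
    geoms = np.asarray(features["geometry"], dtype=object)
    quantities = features[quantity_col].to_numpy(dtype=float)
    if (quantities < 0).any():
        raise InvalidInputError("feature quantities must be non-negative")
    fids = features[id_col].to_numpy()
    n = len(geoms)
    feat_area = shapely.area(geoms)

    zgeoms = zones.geometries
    tree = STRtree(zgeoms)
    fi, zi = tree.query(geoms, predicate="intersects")

    out_f: list[np.ndarray] = []
    out_z: list[np.ndarray] = []
    out_frac: list[np.ndarray] = []

    if len(fi):
        contained = shapely.contains_properly(zgeoms[zi], geoms[fi])
        cf, cz = fi[contained], zi[contained]
        out_f.append(cf)
        out_z.append(cz)
        out_frac.append(np.ones(len(cf)))
        done = np.zeros(n, dtype=bool)
        done[cf] = True
        rest = ~contained & ~done[fi]
        rf, rz = fi[rest], zi[rest]
        if len(rf):
            inter = shapely.area(shapely.intersection(geoms[rf], zgeoms[rz]))
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(feat_area[rf] > 0, inter / feat_area[rf], 0.0)
            keep = frac > 1e-12
            out_f.append(rf[keep])
            out_z.append(rz[keep])
            out_frac.append(frac[keep])

    if out_f:
        all_f = np.concatenate(out_f)
        all_z = np.concatenate(out_z)
        all_frac = np.concatenate(out_frac)
    else:
        all_f = np.empty(0, dtype=int)
        all_z = np.empty(0, dtype=int)
        all_frac = np.empty(0)

    # residual mass per feature -> OUTSIDE
    covered = np.zeros(n)
    np.add.at(covered, all_f, all_frac)
    resid = 1.0 - covered
    out_feats = np.nonzero(resid > 1e-9)[0]

    df = pd.DataFrame(
        {
            "feature_id": fids[all_f],
            "unit_id": zones.unit_ids[all_z],
            "fraction": all_frac,
            "quantity": quantities[all_f] * all_frac,
        }
    )
    if len(out_feats):
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    {
                        "feature_id": fids[out_feats],
                        "unit_id": OUTSIDE,
                        "fraction": resid[out_feats],
                        "quantity": quantities[out_feats] * resid[out_feats],
                    }
                ),
            ],
            ignore_index=True,
        )
    return OverlayTable(df)


def terrain_cell_membership(raster: Raster, zones: ZoneSet) -> np.ndarray:
    """Zone index (into ``zones.df``) containing each cell centre; -1 if none.

    Unlike :func:`proportional_overlay` cells are never split.  Ties (a
    centre exactly on a shared boundary) go to the unit with the smaller
    ``unit_id``.
    """
    if raster.crs != zones.crs:
        raise InvalidInputError("coordinate reference mismatch")
    # visit zones in decreasing unit_id so the smallest id wins ties
    ids = zones.unit_ids
    try:
        order = np.argsort(ids)[::-1]
    except TypeError:
        order = np.argsort(ids.astype(str))[::-1]
    geoms = zones.geometries
    nr, nc = raster.shape
    membership = np.full(nr * nc, -1, dtype=int)

    bounds = shapely.bounds(geoms)
    bbox_area = (bounds[:, 2] - bounds[:, 0]) * (bounds[:, 3] - bounds[:, 1])
    all_rect = bool(
        np.all(np.abs(shapely.area(geoms) - bbox_area) <= 1e-9 * np.maximum(bbox_area, 1.0))
    )
    if all_rect:
        # index arithmetic: centre in [xmin, xmax] x [ymin, ymax], inclusive
        x0, y0 = raster.origin
        cs = raster.cell_size
        mem2 = membership.reshape(nr, nc)
        for zidx in order:
            bx0, by0, bx1, by1 = bounds[zidx]
            c0 = max(0, int(np.ceil((bx0 - x0) / cs - 0.5)))
            c1 = min(nc, int(np.floor((bx1 - x0) / cs - 0.5)) + 1)
            r0 = max(0, int(np.ceil((y0 - by1) / cs - 0.5)))
            r1 = min(nr, int(np.floor((y0 - by0) / cs - 0.5)) + 1)
            if c1 > c0 and r1 > r0:
                mem2[r0:r1, c0:c1] = zidx
        return mem2

    X, Y = raster.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    tree = STRtree(pts)
    for zidx in order:
        hit = tree.query(geoms[zidx], predicate="covers")
        membership[hit] = zidx
    return membership.reshape(raster.shape)


def aggregate_estimate(
    estimate: pd.DataFrame,
    zones: ZoneSet,
    pop_col: str = "pop",
    id_col: str = "tz_id",
) -> tuple[pd.Series, float]:
    """Sum TZ populations per zone unit by proportional-area apportionment.

    Returns (per-unit series indexed like ``zones.df``, outside mass).  The
    total is conserved: per-unit sum + outside = estimate total.
    """
    if estimate.empty:
        logger.warning("aggregate_estimate: empty estimate, returning zeros")
        return pd.Series(0.0, index=zones.unit_ids), 0.0
    table = proportional_overlay(estimate, zones, quantity_col=pop_col, id_col=id_col)
    per_unit = table.per_unit().reindex(zones.unit_ids, fill_value=0.0)
    return per_unit, table.outside()


def landuse_shares(zones: ZoneSet, buildings: pd.DataFrame) -> pd.DataFrame:
    """Per-unit share of building footprint area by land use (R/C/O).

    Buildings are attributed to the unit containing their centroid, matching
    how census blocks own whole buildings.  Units without buildings get all
    shares 0.
    """
    cent = shapely.centroid(np.asarray(buildings["geometry"], dtype=object))
    tree = STRtree(zones.geometries)
    bi, zi = tree.query(cent, predicate="covered_by")
    # first hit wins (partition assumption)
    first = pd.Series(zi, index=bi).groupby(level=0).first()
    shares = pd.DataFrame(
        0.0, index=range(len(zones)), columns=[f"share_{lu}" for lu in LAND_USES]
    )
    areas = buildings["area"].to_numpy(dtype=float)
    lus = buildings["land_use"].to_numpy()
    bidx = first.index.to_numpy()
    zidx = first.to_numpy()
    for lu in LAND_USES:
        sel = lus[bidx] == lu
        if sel.any():
            contrib = pd.Series(areas[bidx[sel]], index=zidx[sel]).groupby(level=0).sum()
            shares.loc[contrib.index, f"share_{lu}"] += contrib.to_numpy()
    tot = shares.sum(axis=1)
    nz = tot > 0
    shares.loc[nz] = shares.loc[nz].div(tot[nz], axis=0)
    shares.insert(0, "unit_id", zones.unit_ids)
    return shares
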