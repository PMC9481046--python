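"""Seeded generator of a toy city with building-level ground-truth population.

The generator emulates the study conditions of a dense, heterogeneous
Latin-American city: a nested census geography (sectors L2 ⊃ sections L1 ⊃
urban blocks L0, blocks separated by road corridors), a North-dense
population gradient, a commercial corridor through the city centre, mixed
residential/commercial/other land use, multi-resolution urban masks with
commission noise (sealed surfaces, pavement) and omission noise (footprints
missing from the cadastre, as in informal settlements), plus valley terrain.

Ground truth: every building carries an integer population
``pop = floor_area x density(x, y) x occupancy(land use) x noise``,
stochastically rounded so census counts are integers while expectations
match the density model.  Census counts at every level are exact sums of
contained buildings (assigned by centroid, never split).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box

from . import io as pio
from .geo_core import InvalidInputError, UrbanMask, ZoneSet
from .raster import Raster, block_mean, coverage_raster, paint_binary, read_geotiff, write_geotiff

MASK_NAMES = ("MR", "HR", "VHR", "3D_VHR", "VHR_LU", "3D_VHR_LU")

FIXTURE_LAYERS = (
    "buildings.geojson",
    "zones_l0.geojson",
    "zones_l1.geojson",
    "zones_l2.geojson",
    "mask_mr.tif",
    "mask_hr.tif",
    "dem.tif",
    "slope.tif",
    "roads.geojson",
    "vegetation.geojson",
    "establishments.geojson",
)


class ConfigError(ValueError):
    pass


@dataclass
class CityConfig:
    """Generator parameters; defaults define the standard study conditions."""

    width: float = 4000.0
    height: float = 4000.0
    # census partition: n_l2 x n_l2 sectors, each split 2x2 into sections,
    # each section split blocks_per_l1 x blocks_per_l1 into road-separated blocks
    n_l2: int = 6
    n_l1_per_l2: int = 2
    blocks_per_l1: int = 3
    arterial_width: float = 16.0
    local_road_width: float = 10.0
    # buildings
    parcel_size: float = 50.0
    p_build: float = 0.78
    footprint_area_mean: float = 400.0      # log-normal mean, m^2
    footprint_area_sigma: float = 0.5      # log-scale sd
    floors_mean: float = 2.5                # geometric distribution mean
    floors_cap: int = 30
    # land use
    p_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)  # R, C, O
    corridor_width: float = 600.0           # central commercial corridor
    n_other_clusters: int = 8
    other_cluster_radius: float = 250.0
    p_empty_block: float = 0.03             # institutional blocks, zero population
    # population model
    density_base: float = 0.03              # persons / m^2 habitable floor area
    density_ratio_ns: float = 8.0           # North/South density factor
    occupancy: tuple[float, float, float] = (1.0, 0.4, 0.3)   # w_R, w_C, w_O
    noise_sigma: float = 0.25               # log-normal, mean-one
    landuse_noise_sigma: float = 0.6        # extra C/O mixed-use variability
    integer_pops: bool = True
    # masks
    mr_cell: float = 30.0
    hr_cell: float = 3.0
    mr_commission: float = 0.35
    hr_commission: float = 0.25
    mr_omission: float = 0.02
    hr_omission: float = 0.02
    pavement_buffer: float = 8.0
    coverage_threshold: float = 0.5
    # coarse mixed pixels classify as urban at lower purity (generous
    # satellite classification), so the MR mask over-includes most
    mr_threshold: float = 0.25
    # terrain / ancillary
    dem_cell: float = 10.0
    p_veg_parcel: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.p_mix) - 1.0) > 1e-9:
            raise ConfigError("land-use mixture proportions must sum to 1")
        for w in (*self.occupancy, self.mr_commission, self.hr_commission,
                  self.mr_omission, self.hr_omission, self.p_build,
                  self.p_empty_block, self.p_veg_parcel):
            if not 0.0 <= w <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if min(self.n_l2, self.n_l1_per_l2, self.blocks_per_l1) < 1:
            raise ConfigError("partition counts must be positive")
        l1 = self.width / (self.n_l2 * self.n_l1_per_l2)
        needed = self.arterial_width + self.blocks_per_l1 * (self.local_road_width + 20.0)
        if l1 < needed:
            raise ConfigError("more blocks than fit with the road spacing")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.width, self.height)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SyntheticCity:
    config: CityConfig
    buildings: pd.DataFrame          # building_id, geometry, area, floors, land_use, pop
    zones_l0: ZoneSet
    zones_l1: ZoneSet
    zones_l2: ZoneSet
    mask_mr: Raster
    mask_hr: Raster
    roads: pd.DataFrame              # axis LineStrings with width attribute
    vegetation: pd.DataFrame
    establishments: pd.DataFrame     # point geometries
    dem: Raster
    slope: Raster

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.config.extent

    def road_polygons(self) -> np.ndarray:
        geoms = np.asarray(self.roads["geometry"], dtype=object)
        widths = self.roads["width"].to_numpy(dtype=float)
        return np.array(
            [g.buffer(w / 2.0, cap_style="flat", join_style="mitre")
             for g, w in zip(geoms, widths)],
            dtype=object,
        )

    def road_intersections(self) -> np.ndarray:
        """Point geometries where road axes cross or meet."""
        geoms = np.asarray(self.roads["geometry"], dtype=object)
        tree = shapely.STRtree(geoms)
        ai, bi = tree.query(geoms, predicate="intersects")
        pts = []
        for a, b in zip(ai, bi):
            if a >= b:
                continue
            inter = shapely.intersection(geoms[a], geoms[b])
            for p in getattr(inter, "geoms", [inter]):
                if p.geom_type == "Point":
                    pts.append((round(p.x, 6), round(p.y, 6)))
        uniq = sorted(set(pts))
        return shapely.points([p[0] for p in uniq], [p[1] for p in uniq])

    def mask(self, name: str) -> UrbanMask:
        """One of the six urban masks (MR, HR, VHR, 3D_VHR, VHR_LU, 3D_VHR_LU)."""
        if name == "MR":
            return UrbanMask("RASTER", "AREA", raster=self.mask_mr, name=name)
        if name == "HR":
            return UrbanMask("RASTER", "AREA", raster=self.mask_hr, name=name)
        if name not in MASK_NAMES:
            raise InvalidInputError(f"unknown mask {name!r}")
        b = self.buildings
        if "LU" not in name:
            b = b.drop(columns=["land_use"])
        dim = "VOLUME" if name.startswith("3D") else "AREA"
        return UrbanMask("FOOTPRINT", dim, buildings=b, name=name)

    def landuse_zones(self) -> pd.DataFrame:
        """Block polygons labelled with their dominant building land use.

        Emulates the 'homogeneous physical zones' land-use polygons used by
        the coarser-resolution covariates.
        """
        from .geo_core import landuse_shares

        shares = landuse_shares(self.zones_l0, self.buildings)
        arr = shares[["share_R", "share_C", "share_O"]].to_numpy()
        labels = np.array(["R", "C", "O"])[arr.argmax(axis=1)]
        keep = arr.sum(axis=1) > 0
        return pd.DataFrame(
            {"geometry": self.zones_l0.geometries[keep], "land_use": labels[keep]}
        )


def _partition(cfg: CityConfig):
    """L2/L1 tiles and road-separated L0 block rectangles with parent links."""
    n1 = cfg.n_l2 * cfg.n_l1_per_l2
    s1x = cfg.width / n1
    s1y = cfg.height / n1
    l2_rows = []
    l1_rows = []
    l0_rows = []
    nb = cfg.blocks_per_l1
    for i2 in range(cfg.n_l2 * cfg.n_l2):
        r2, c2 = divmod(i2, cfg.n_l2)
        x0 = c2 * cfg.n_l1_per_l2 * s1x
        y0 = r2 * cfg.n_l1_per_l2 * s1y
        l2_id = f"L2_{i2:02d}"
        l2_rows.append(
            {"unit_id": l2_id,
             "geometry": box(x0, y0, x0 + cfg.n_l1_per_l2 * s1x, y0 + cfg.n_l1_per_l2 * s1y)}
        )
        for j in range(cfg.n_l1_per_l2 ** 2):
            r1, c1 = divmod(j, cfg.n_l1_per_l2)
            i1 = len(l1_rows)
            xa = x0 + c1 * s1x
            ya = y0 + r1 * s1y
            l1_id = f"L1_{i1:03d}"
            l1_rows.append(
                {"unit_id": l1_id, "parent_id": l2_id,
                 "geometry": box(xa, ya, xa + s1x, ya + s1y)}
            )
            # blocks: arterial half-width margin at tile edges, local roads inside
            ha = cfg.arterial_width / 2.0
            hl = cfg.local_road_width / 2.0
            bw = (s1x - 2 * ha - (nb - 1) * 2 * hl) / nb
            bh = (s1y - 2 * ha - (nb - 1) * 2 * hl) / nb
            for k in range(nb * nb):
                rb, cb = divmod(k, nb)
                bx = xa + ha + cb * (bw + 2 * hl)
                by = ya + ha + rb * (bh + 2 * hl)
                l0_rows.append(
                    {"unit_id": f"L0_{len(l0_rows):04d}", "parent_id": l1_id,
                     "geometry": box(bx, by, bx + bw, by + bh)}
                )
    return pd.DataFrame(l0_rows), pd.DataFrame(l1_rows), pd.DataFrame(l2_rows), (s1x, s1y)


def _road_axes(cfg: CityConfig, s1: tuple[float, float]) -> pd.DataFrame:
    """Arterial axes along L1 tile boundaries, local axes between blocks."""
    from shapely.geometry import LineString

    s1x, s1y = s1
    n1 = cfg.n_l2 * cfg.n_l1_per_l2
    rows = []
    for i in range(n1 + 1):
        x = i * s1x
        rows.append({"geometry": LineString([(x, 0), (x, cfg.height)]),
                     "width": cfg.arterial_width, "kind": "arterial"})
        y = i * s1y
        rows.append({"geometry": LineString([(0, y), (cfg.width, y)]),
                     "width": cfg.arterial_width, "kind": "arterial"})
    nb = cfg.blocks_per_l1
    ha = cfg.arterial_width / 2.0
    hl = cfg.local_road_width / 2.0
    bw = (s1x - 2 * ha - (nb - 1) * 2 * hl) / nb
    bh = (s1y - 2 * ha - (nb - 1) * 2 * hl) / nb
    for t in range(n1 * n1):
        r1, c1 = divmod(t, n1)
        xa, ya = c1 * s1x, r1 * s1y
        for k in range(1, nb):
            x = xa + ha + k * bw + (2 * k - 1) * hl
            rows.append({"geometry": LineString([(x, ya), (x, ya + s1y)]),
                         "width": cfg.local_road_width, "kind": "local"})
            y = ya + ha + k * bh + (2 * k - 1) * hl
            rows.append({"geometry": LineString([(xa, y), (xa + s1x, y)]),
                         "width": cfg.local_road_width, "kind": "local"})
    return pd.DataFrame(rows)


def _density(cfg: CityConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Persons per m^2 of habitable floor area at (x, y); North-dense."""
    g = np.log(cfg.density_ratio_ns)
    return cfg.density_base * np.exp(g * (np.asarray(y) / cfg.height - 0.5))


def generate_city(config: CityConfig | None = None, seed: int | None = None) -> SyntheticCity:
    """Build the full synthetic city; deterministic for a fixed seed."""
    cfg = config or CityConfig()
    if seed is not None:
        cfg = CityConfig(**{**cfg.to_dict(), "seed": int(seed)})
    rng = np.random.default_rng(cfg.seed)

    l0_df, l1_df, l2_df, s1 = _partition(cfg)
    roads = _road_axes(cfg, s1)

    # --- buildings -------------------------------------------------------
    wR, wC, wO = cfg.occupancy
    pR, pC, pO = cfg.p_mix
    other_centers = rng.uniform(
        [0, 0], [cfg.width, cfg.height], size=(cfg.n_other_clusters, 2)
    )
    empty_blocks = rng.random(len(l0_df)) < cfg.p_empty_block

    # structural density tracks population density (denser north: more
    # parcels built, taller buildings, less vegetation), so built-up
    # covariates genuinely carry the density signal a weight model needs
    u = np.linspace(0.0, 1.0, 201)
    g = np.log(cfg.density_ratio_ns)
    densf_u = np.exp(g * (u - 0.5))
    norm_build = float(np.mean(densf_u**0.5))
    norm_floors = float(np.mean(densf_u**0.7))

    b_rows = []
    veg_rows = []
    for bi, brow in l0_df.iterrows():
        bx0, by0, bx1, by1 = brow["geometry"].bounds
        nx = max(1, int(round((bx1 - bx0) / cfg.parcel_size)))
        ny = max(1, int(round((by1 - by0) / cfg.parcel_size)))
        pw, ph = (bx1 - bx0) / nx, (by1 - by0) / ny
        for p in range(nx * ny):
            pr, pc = divmod(p, nx)
            px0, py0 = bx0 + pc * pw, by0 + pr * ph
            densf = float(
                _density(cfg, px0 + pw / 2, py0 + ph / 2) / cfg.density_base
            )
            p_build_loc = min(max(cfg.p_build * densf**0.5 / norm_build, 0.2), 0.95)
            if rng.random() >= p_build_loc:
                p_veg_loc = min(max(cfg.p_veg_parcel * (2.2 - densf), 0.05), 0.6)
                if rng.random() < p_veg_loc:
                    veg_rows.append(
                        {"geometry": box(px0 + 2, py0 + 2, px0 + pw - 2, py0 + ph - 2)}
                    )
                continue
            target = rng.lognormal(
                np.log(cfg.footprint_area_mean) - cfg.footprint_area_sigma**2 / 2,
                cfg.footprint_area_sigma,
            )
            aspect = rng.uniform(0.6, 1.6)
            w = min(np.sqrt(target * aspect), pw - 4.0)
            h = min(target / w, ph - 4.0)
            w = max(w, 4.0)
            h = max(h, 4.0)
            ox = rng.uniform(2.0, max(pw - w - 2.0, 2.0 + 1e-9))
            oy = rng.uniform(2.0, max(ph - h - 2.0, 2.0 + 1e-9))
            cx, cy = px0 + ox + w / 2, py0 + oy + h / 2
            # land-use mixture with spatial clustering
            in_corridor = abs(cx - cfg.width / 2) < cfg.corridor_width / 2
            mult = np.array([0.1, 8.0, 1.0]) if in_corridor else np.array([1.0, 0.3, 0.8])
            d2 = np.sum((other_centers - [cx, cy]) ** 2, axis=1)
            if (d2 < cfg.other_cluster_radius**2).any():
                mult = mult * np.array([0.5, 1.0, 6.0])
            weights = np.array([pR, pC, pO]) * mult
            lu = rng.choice(["R", "C", "O"], p=weights / weights.sum())
            floors_mean_loc = 1.0 + (cfg.floors_mean - 1.0) * densf**0.7 / norm_floors
            floors = min(int(rng.geometric(1.0 / floors_mean_loc)), cfg.floors_cap)
            b_rows.append(
                {"building_id": f"B{len(b_rows):05d}",
                 "geometry": box(px0 + ox, py0 + oy, px0 + ox + w, py0 + oy + h),
                 "floors": floors, "land_use": lu, "block_idx": bi,
                 "empty": bool(empty_blocks[bi])}
            )
    buildings = pd.DataFrame(b_rows)
    buildings.loc[buildings["empty"], "land_use"] = "O"
    buildings["area"] = shapely.area(np.asarray(buildings["geometry"], dtype=object))

    # --- ground-truth population ----------------------------------------
    cents = shapely.centroid(np.asarray(buildings["geometry"], dtype=object))
    cx = shapely.get_x(cents)
    cy = shapely.get_y(cents)
    dens = _density(cfg, cx, cy)
    occ = buildings["land_use"].map({"R": wR, "C": wC, "O": wO}).to_numpy(dtype=float)
    size = buildings["area"].to_numpy() * buildings["floors"].to_numpy()
    s = cfg.noise_sigma
    noise = rng.lognormal(-s**2 / 2, s, len(buildings)) if s > 0 else np.ones(len(buildings))
    slu = cfg.landuse_noise_sigma
    if slu > 0:
        lu_noise = np.where(
            buildings["land_use"].isin(["C", "O"]).to_numpy(),
            rng.lognormal(-slu**2 / 2, slu, len(buildings)),
            1.0,
        )
    else:
        lu_noise = np.ones(len(buildings))
    pop = size * dens * occ * noise * lu_noise
    pop[buildings["empty"].to_numpy()] = 0.0
    if cfg.integer_pops:
        frac, whole = np.modf(pop)
        pop = whole + (rng.random(len(pop)) < frac)
    buildings["pop"] = pop
    buildings = buildings.drop(columns=["empty"])

    # --- ancillary layers ------------------------------------------------
    vegetation = pd.DataFrame(veg_rows if veg_rows else {"geometry": []})
    est_rows = []
    lam = {"R": 0.1, "C": 2.0, "O": 0.5}
    for geom, lu in zip(buildings["geometry"], buildings["land_use"]):
        k = rng.poisson(lam[lu])
        if k:
            gx0, gy0, gx1, gy1 = geom.bounds
            xs = rng.uniform(gx0, gx1, k)
            ys = rng.uniform(gy0, gy1, k)
            est_rows.extend({"geometry": p} for p in shapely.points(xs, ys))
    establishments = pd.DataFrame(est_rows if est_rows else {"geometry": []})

    # --- terrain ----------------------------------------------------------
    nr = int(np.ceil(cfg.height / cfg.dem_cell))
    nc = int(np.ceil(cfg.width / cfg.dem_cell))
    xs = (np.arange(nc) + 0.5) * cfg.dem_cell
    ys = cfg.height - (np.arange(nr) + 0.5) * cfg.dem_cell
    X, Y = np.meshgrid(xs, ys)
    elev = 1500.0 + 600.0 * ((X - cfg.width / 2) / (cfg.width / 2)) ** 2
    bumps = ndimage.gaussian_filter(rng.normal(0, 1, (nr, nc)), sigma=8) * 120.0
    elev = elev + bumps
    dzdy, dzdx = np.gradient(elev, -cfg.dem_cell, cfg.dem_cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    dem = Raster(elev, (0.0, cfg.height), cfg.dem_cell)
    slope_r = Raster(slope, (0.0, cfg.height), cfg.dem_cell)

    # --- census + masks ---------------------------------------------------
    city = SyntheticCity(
        config=cfg,
        buildings=buildings.drop(columns=["block_idx"]),
        zones_l0=ZoneSet("L0", l0_df.assign(pop=0.0)),
        zones_l1=ZoneSet("L1", l1_df.assign(pop=0.0)),
        zones_l2=ZoneSet("L2", l2_df.assign(pop=0.0)),
        mask_mr=Raster(np.zeros((1, 1)), (0.0, cfg.height), cfg.mr_cell),
        mask_hr=Raster(np.zeros((1, 1)), (0.0, cfg.height), cfg.hr_cell),
        roads=roads,
        vegetation=vegetation,
        establishments=establishments,
        dem=dem,
        slope=slope_r,
    )
    l0, l1, l2 = derive_census(city)
    city.zones_l0, city.zones_l1, city.zones_l2 = l0, l1, l2
    city.mask_mr = degrade_to_mask(
        city, cfg.mr_cell, cfg.mr_commission, cfg.mr_omission, seed=cfg.seed + 101,
        threshold=cfg.mr_threshold,
    )
    city.mask_hr = degrade_to_mask(
        city, cfg.hr_cell, cfg.hr_commission, cfg.hr_omission, seed=cfg.seed + 102
    )
    return city


def derive_census(city: SyntheticCity) -> tuple[ZoneSet, ZoneSet, ZoneSet]:
    """Census counts at L0/L1/L2 by summing buildings (centroid membership)."""
    b = city.buildings
    cents = shapely.centroid(np.asarray(b["geometry"], dtype=object))
    tree = shapely.STRtree(city.zones_l0.geometries)
    bi, zi = tree.query(cents, predicate="covered_by")
    first = pd.Series(zi, index=bi).groupby(level=0).first()
    pops = np.zeros(len(city.zones_l0))
    np.add.at(pops, first.to_numpy(), b["pop"].to_numpy()[first.index.to_numpy()])

    l0 = ZoneSet("L0", city.zones_l0.df.assign(pop=pops))
    l1_sum = l0.df.groupby("parent_id")["pop"].sum()
    l1 = ZoneSet(
        "L1",
        city.zones_l1.df.assign(
            pop=city.zones_l1.df["unit_id"].map(l1_sum).fillna(0.0).to_numpy()
        ),
    )
    l2_sum = l1.df.groupby("parent_id")["pop"].sum()
    l2 = ZoneSet(
        "L2",
        city.zones_l2.df.assign(
            pop=city.zones_l2.df["unit_id"].map(l2_sum).fillna(0.0).to_numpy()
        ),
    )
    return l0, l1, l2


def degrade_to_mask(
    city: SyntheticCity,
    cell_size: float,
    commission: float,
    omission: float,
    seed: int = 0,
    threshold: float | None = None,
    pavement: float | None = None,
) -> Raster:
    """Binary urban mask at ``cell_size`` from footprints ∪ roads, with noise.

    A cell is urban if the sealed-surface coverage (buildings buffered by the
    pavement width, plus road corridors) reaches the threshold.  Commission
    flips candidate cells adjacent to urban coverage with the given rate;
    omission drops building-only cells (no road coverage), emulating cadastre
    gaps over informal settlements.
    """
    cfg = city.config
    if not 0.0 <= commission <= 1.0 or not 0.0 <= omission <= 1.0:
        raise InvalidInputError("rates must lie in [0, 1]")
    thr = cfg.coverage_threshold if threshold is None else threshold
    pav = cfg.pavement_buffer if pavement is None else pavement
    rng = np.random.default_rng(seed)
    extent = cfg.extent

    bgeoms = np.asarray(city.buildings["geometry"], dtype=object)
    if pav > 0:
        sealed = np.array(
            [g.buffer(pav, cap_style="square", join_style="mitre") for g in bgeoms],
            dtype=object,
        )
    else:
        sealed = bgeoms
    road_polys = city.road_polygons() if len(city.roads) else np.array([], dtype=object)

    build_cov = coverage_raster(bgeoms, extent, cell_size).values
    sealed_cov = coverage_raster(sealed, extent, cell_size).values
    road_cov = (
        coverage_raster(road_polys, extent, cell_size).values
        if len(road_polys)
        else np.zeros_like(build_cov)
    )
    total = np.minimum(sealed_cov + road_cov, 1.0)
    urban = total >= thr

    if commission > 0:
        near = ndimage.binary_dilation(urban) | (total > 0)
        cand = near & ~urban
        urban = urban | (cand & (rng.random(urban.shape) < commission))
    if omission > 0:
        building_only = urban & (build_cov > 0) & (road_cov == 0)
        drop = building_only & (rng.random(urban.shape) < omission)
        urban = urban & ~drop
    return Raster(urban.astype(np.uint8), (extent[0], extent[3]), cell_size)


def write_fixture(city: SyntheticCity, directory) -> None:
    """Write all layers plus a provenance manifest; round-trip exact."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pio.write_geojson(d / "buildings.geojson", city.buildings)
    pio.write_zones(d / "zones_l0.geojson", city.zones_l0)
    pio.write_zones(d / "zones_l1.geojson", city.zones_l1)
    pio.write_zones(d / "zones_l2.geojson", city.zones_l2)
    write_geotiff(d / "mask_mr.tif", city.mask_mr)
    write_geotiff(d / "mask_hr.tif", city.mask_hr)
    write_geotiff(d / "dem.tif", city.dem)
    write_geotiff(d / "slope.tif", city.slope)
    pio.write_geojson(d / "roads.geojson", city.roads)
    pio.write_geojson(d / "vegetation.geojson", city.vegetation)
    pio.write_geojson(d / "establishments.geojson", city.establishments)
    manifest = {
        "seed": city.config.seed,
        "config": city.config.to_dict(),
        "config_hash": city.config.content_hash(),
        "layers": list(FIXTURE_LAYERS),
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_fixture(directory) -> SyntheticCity:
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = CityConfig(**manifest["config"])
    buildings = pio.read_geojson(d / "buildings.geojson")
    buildings["area"] = shapely.area(np.asarray(buildings["geometry"], dtype=object))
    veg = pio.read_geojson(d / "vegetation.geojson")
    est = pio.read_geojson(d / "establishments.geojson")
    return SyntheticCity(
        config=cfg,
        buildings=buildings,
        zones_l0=pio.read_zones(d / "zones_l0.geojson", "L0"),
        zones_l1=pio.read_zones(d / "zones_l1.geojson", "L1"),
        zones_l2=pio.read_zones(d / "zones_l2.geojson", "L2"),
        mask_mr=read_geotiff(d / "mask_mr.tif"),
        mask_hr=read_geotiff(d / "mask_hr.tif"),
        roads=pio.read_geojson(d / "roads.geojson"),
        vegetation=veg if len(veg) else pd.DataFrame({"geometry": []}),
        establishments=est if len(est) else pd.DataFrame({"geometry": []}),
        dem=read_geotiff(d / "dem.tif"),
        slope=read_geotiff(d / "slope.tif"),
    )
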