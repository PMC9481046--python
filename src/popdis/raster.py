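"""Minimal in-memory raster model and single-band GeoTIFF I/O.

Rasters are north-up with square cells in a planar metric frame.  ``values``
row 0 is the northernmost row; ``origin`` is the (x, y) map coordinate of the
*top-left corner* of the top-left cell.  Georeferencing round-trips through
GeoTIFF ModelPixelScale / ModelTiepoint tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

NODATA = -1.0

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass
class Raster:
    values: np.ndarray            # (nrows, ncols)
    origin: tuple[float, float]   # top-left corner (x, y)
    cell_size: float
    nodata: float = NODATA
    crs: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster footprint."""
        nr, nc = self.values.shape
        x0, y0 = self.origin
        return (x0, y0 - nr * self.cell_size, x0 + nc * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of every cell centre as (X, Y) 2-D arrays."""
        nr, nc = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy(self, values: np.ndarray | None = None) -> "Raster":
        return Raster(
            self.values.copy() if values is None else np.asarray(values),
            self.origin,
            self.cell_size,
            self.nodata,
            self.crs,
        )


def paint_binary(
    geoms,
    extent: tuple[float, float, float, float],
    base: float = 1.0,
) -> np.ndarray:
    """Boolean canvas at ``base`` resolution marking cells covered by geoms.

    Axis-aligned rectangles (the dominant case for synthetic cities) are
    painted by index slicing; other polygons fall back to a per-geometry
    centre-in-polygon test on their bounding window.
    """
    import shapely

    xmin, ymin, xmax, ymax = extent
    ncols = int(np.ceil((xmax - xmin) / base))
    nrows = int(np.ceil((ymax - ymin) / base))
    canvas = np.zeros((nrows, ncols), dtype=bool)
    geoms = np.asarray(geoms, dtype=object)
    if geoms.size == 0:
        return canvas
    bounds = shapely.bounds(geoms)
    areas = shapely.area(geoms)
    bbox_areas = (bounds[:, 2] - bounds[:, 0]) * (bounds[:, 3] - bounds[:, 1])
    is_rect = np.abs(areas - bbox_areas) <= 1e-9 * np.maximum(bbox_areas, 1.0)
    for g, (bx0, by0, bx1, by1), rect in zip(geoms, bounds, is_rect):
        c0 = max(0, int(np.floor((bx0 - xmin) / base)))
        c1 = min(ncols, int(np.ceil((bx1 - xmin) / base)))
        r0 = max(0, int(np.floor((ymax - by1) / base)))
        r1 = min(nrows, int(np.ceil((ymax - by0) / base)))
        if c1 <= c0 or r1 <= r0:
            continue
        if rect:
            # cover cells whose centre lies in the rectangle
            cc0 = max(0, int(np.floor((bx0 - xmin) / base + 0.5)))
            cc1 = min(ncols, int(np.ceil((bx1 - xmin) / base - 0.5)))
            rr0 = max(0, int(np.floor((ymax - by1) / base + 0.5)))
            rr1 = min(nrows, int(np.ceil((ymax - by0) / base - 0.5)))
            canvas[rr0:max(rr0, rr1), cc0:max(cc0, cc1)] = True
        else:
            xs = xmin + (np.arange(c0, c1) + 0.5) * base
            ys = ymax - (np.arange(r0, r1) + 0.5) * base
            X, Y = np.meshgrid(xs, ys)
            inside = shapely.covers(g, shapely.points(X.ravel(), Y.ravel()))
            canvas[r0:r1, c0:c1] |= inside.reshape(r1 - r0, c1 - c0)
    return canvas


def block_mean(canvas: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a fine canvas to coarse cells by mean (pads with zeros)."""
    nr, nc = canvas.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    arr = np.asarray(canvas, dtype=float)
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)))
    nr2, nc2 = arr.shape
    return arr.reshape(nr2 // factor, factor, nc2 // factor, factor).mean(axis=(1, 3))


def coverage_raster(
    geoms,
    extent: tuple[float, float, float, float],
    cell_size: float,
    base: float = 1.0,
) -> Raster:
    """Coverage fraction in [0, 1] of the geometry union per square cell."""
    factor = int(round(cell_size / base))
    if factor < 1:
        factor, base = 1, cell_size
    canvas = paint_binary(geoms, extent, base=cell_size / factor)
    xmin, _, _, ymax = extent
    return Raster(block_mean(canvas, factor), (xmin, ymax), cell_size)


def write_geotiff(path, raster: Raster) -> None:
    """Write a single-band GeoTIFF with pixel-scale and tiepoint tags."""
    scale = (float(raster.cell_size), float(raster.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(raster.origin[0]), float(raster.origin[1]), 0.0)
    values = np.asarray(raster.values)
    if values.dtype == bool:
        values = values.astype(np.uint8)
    tifffile.imwrite(
        path,
        values,
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, scale),
            (_MODEL_TIEPOINT, "d", 6, tiepoint),
        ],
    )


def read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy, _ = tags[_MODEL_PIXEL_SCALE].value
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells not supported")
        tp = tags[_MODEL_TIEPOINT].value
    return Raster(values, (float(tp[3]), float(tp[4])), float(sx))
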