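"""GeoJSON vector I/O for zones, buildings and ancillary layers.

Attribute names are fixed: ``unit_id``, ``parent_id``, ``pop`` for zones;
``building_id``, ``floors``, ``land_use`` in {R, C, O} for buildings.
Coordinates are planar metric; no reprojection is performed.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .geo_core import ZoneSet


def _features_to_df(features: list[dict]) -> pd.DataFrame:
    rows = []
    for feat in features:
        props = dict(feat.get("properties") or {})
        props["geometry"] = shape(feat["geometry"])
        rows.append(props)
    return pd.DataFrame(rows)


def _df_to_geojson(df: pd.DataFrame, precision: int | None = None) -> dict:
    features = []
    for _, row in df.iterrows():
        props = {k: _jsonify(v) for k, v in row.items() if k != "geometry"}
        geom = row["geometry"]
        if precision is not None:
            geom = shapely.set_precision(geom, 10.0 ** (-precision))
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    return {"type": "FeatureCollection", "features": features}


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def write_geojson(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        json.dump(_df_to_geojson(df), fh)


def read_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        data = json.load(fh)
    return _features_to_df(data["features"])


def write_zones(path, zones: ZoneSet) -> None:
    cols = [c for c in zones.df.columns if c != "area"]
    write_geojson(path, zones.df[cols])


def read_zones(path, level: str) -> ZoneSet:
    return ZoneSet(level, read_geojson(path))
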