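"""GeoJSON-backed vector I/O.

Layers are held in memory as pandas DataFrames with a ``geometry`` column of
shapely objects; on disk they are GeoJSON FeatureCollections in the package's
planar metric frame.
"""

from __future__ import annotations

import json

import pandas as pd
import shapely
from shapely.geometry import mapping, shape


def write_geojson(df: pd.DataFrame, path) -> None:
    feats = []
    for _, row in df.iterrows():
        props = {k: v for k, v in row.items() if k != "geometry"}
        feats.append(
            {"type": "Feature", "geometry": mapping(row["geometry"]), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def geometry_frame(geoms, **columns) -> pd.DataFrame:
    df = pd.DataFrame({"geometry": list(geoms)})
    for k, v in columns.items():
        df[k] = v
    return df


def total_length(geoms) -> float:
    return float(sum(shapely.length(g) for g in geoms))
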