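"""Beaver Forage Index (BFI): landcover suitability rasters and reach summaries.

Up to four landcover sources — a fine categorical vector layer, a categorical
raster, a percent tree-cover raster and a woody-linear-features vector layer
— are reclassified to integer suitability 0-5, rasterised/aligned to a
common 5 m grid, and composited: one declared priority source wins wherever
it has data; elsewhere the maximum of the remaining coincident sources is
used; cells with no data in any source score 0 (no vegetation).

Reach-level forage is summarised in two search areas, 10 m (streamside) and
40 m (riparian) from the bank, each extended 100 m up- and downstream along
the network, as the mean of the top 50% of cell values (ceil(k/2) cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import shapely
import shapely.ops
import yaml

from .grid import RasterGrid, rasterize_features, resample_nearest, template_like


@dataclass
class SuitabilityTable:
    """Class-label -> suitability (0-5) mapping for one landcover source.

    ``bands`` (for percent-cover sources) is a list of (low, high, value)
    with half-open intervals (low, high] except the first, which includes
    its lower bound.
    """

    source_id: str
    classes: dict[str, int] | None = None
    bands: list[tuple[float, float, int]] | None = None
    default: int | None = None

    def __post_init__(self):
        vals = list((self.classes or {}).values()) + [v for *_, v in (self.bands or [])]
        if any(v not in range(6) for v in vals):
            raise ValueError("suitability values must be integers 0-5")
        if self.bands:
            b = sorted(self.bands)
            for (l1, h1, _), (l2, _, _) in zip(b, b[1:]):
                if l2 < h1:
                    raise ValueError("percent bands overlap")

    def value_for_class(self, label: str) -> int:
        if self.classes and label in self.classes:
            return self.classes[label]
        if self.default is not None:
            return self.default
        raise KeyError(label)

    def value_for_percent(self, pct) -> np.ndarray:
        pct = np.asarray(pct, dtype=float)
        out = np.full(pct.shape, -1, dtype=float)
        for i, (lo, hi, val) in enumerate(sorted(self.bands)):
            sel = (pct > lo) & (pct <= hi) if i else (pct >= lo) & (pct <= hi)
            out[sel] = val
        if self.default is not None:
            out[out < 0] = self.default
        elif np.any(out < 0):
            raise ValueError("percent values outside all declared bands")
        return out


def load_suitability_tables(path=None) -> dict[str, SuitabilityTable]:
    """Load the shipped (or a user-supplied) suitability configuration."""
    if path is None:
        with resources.files("damcap.data").joinpath("suitability.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    tables = {}
    for sid, entry in raw["sources"].items():
        tables[sid] = SuitabilityTable(
            source_id=sid,
            classes=entry.get("classes"),
            bands=[tuple(b) for b in entry["bands"]] if "bands" in entry else None,
            default=entry.get("default"),
        )
    return tables


def reclassify_source(layer, table: SuitabilityTable):
    """Substitute class labels (or percent values) with suitability values.

    Vector layers are DataFrames with ``geometry`` and ``landclass`` columns
    and return (geometry, value) DataFrames; rasters map to rasters.
    Geometry and raster footprints are unchanged. Unmapped labels without a
    declared default raise, listing every offending label.
    """
    if isinstance(layer, RasterGrid):
        if table.bands is not None:
            data = np.where(
                layer.data == layer.nodata, layer.nodata, 0.0
            )
            valid = layer.data != layer.nodata
            data[valid] = table.value_for_percent(layer.data[valid])
            return layer.copy(data=data)
        out = layer.copy()
        valid = layer.data != layer.nodata
        labels = np.unique(layer.data[valid])
        missing = [
            str(l) for l in labels
            if str(int(l)) not in (table.classes or {}) and table.default is None
        ]
        if missing:
            raise KeyError(f"unmapped classes in {table.source_id}: {missing}")
        lut = {l: table.value_for_class(str(int(l))) for l in labels}
        for l, v in lut.items():
            out.data[layer.data == l] = v
        return out

    missing = sorted(
        {
            lbl
            for lbl in layer["landclass"]
            if lbl not in (table.classes or {}) and table.default is None
        }
    )
    if missing:
        raise KeyError(f"unmapped classes in {table.source_id}: {missing}")
    out = layer.copy()
    out["value"] = [table.value_for_class(lbl) for lbl in layer["landclass"]]
    return out


def rasterize_and_align(layers, template: RasterGrid) -> list[RasterGrid]:
    """Rasterise vector suitability layers and resample raster ones onto a
    shared 5 m grid (nearest neighbour, cell-centre-in-polygon burning)."""
    grids = []
    for layer in layers:
        if isinstance(layer, RasterGrid):
            if (layer.cell_size, layer.x_origin, layer.y_origin, layer.shape) == (
                template.cell_size,
                template.x_origin,
                template.y_origin,
                template.shape,
            ):
                grids.append(layer)
            else:
                grids.append(resample_nearest(layer, template))
        else:
            feats = list(zip(layer["geometry"], layer["value"]))
            grids.append(rasterize_features(feats, template))
    return grids


def composite_bfi(grids: list[RasterGrid], priority_index: int = 0) -> RasterGrid:
    """Composite aligned suitability grids into the BFI.

    The priority grid wins wherever it holds data; otherwise the maximum of
    the remaining coincident grids applies; cells with no data anywhere
    score 0.
    """
    if not grids:
        raise ValueError("no grids to composite")
    template = grids[priority_index]
    out = template_like(template, fill=0.0)
    rest = np.full(template.shape, -1.0)
    for i, g in enumerate(grids):
        if i == priority_index:
            continue
        valid = g.data != g.nodata
        rest[valid] = np.maximum(rest[valid], g.data[valid])
    out.data[rest >= 0] = rest[rest >= 0]
    pvalid = template.data != template.nodata
    out.data[pvalid] = template.data[pvalid]
    out.nodata = -9999.0
    return out


def top_half_mean(values: np.ndarray) -> float:
    """Mean of the top 50% (ceil(k/2) cells) of sampled values."""
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    k = len(v)
    if k == 0:
        return 0.0
    return float(v[: int(np.ceil(k / 2))].mean())


def _extend_along_network(reach_geom, reaches_df: pd.DataFrame, distance: float):
    """Geometry of ``reach_geom`` plus up to ``distance`` metres of the
    adjoining network walked through reach endpoints in both directions."""
    def key(pt):
        return (round(pt[0], 3), round(pt[1], 3))

    # adjacency: endpoint -> [(other endpoint, geometry)]
    adj: dict[tuple, list] = {}
    for g in reaches_df["geometry"]:
        a, b = key(g.coords[0]), key(g.coords[-1])
        adj.setdefault(a, []).append((b, g))
        adj.setdefault(b, []).append((a, g))

    pieces = [reach_geom]
    start, end = key(reach_geom.coords[0]), key(reach_geom.coords[-1])
    for tip, avoid in ((start, end), (end, start)):
        frontier = [(tip, 0.0, reach_geom)]
        seen = {id(reach_geom)}
        while frontier:
            node, used, came_from = frontier.pop()
            for other, g in adj.get(node, []):
                if id(g) in seen:
                    continue
                seen.add(id(g))
                remaining = distance - used
                if remaining <= 0:
                    continue
                if g.length <= remaining:
                    pieces.append(g)
                    frontier.append((other, used + g.length, g))
                else:
                    # walk only part-way into this neighbour
                    if key(g.coords[0]) == node:
                        pieces.append(shapely.ops.substring(g, 0, remaining))
                    else:
                        pieces.append(shapely.ops.substring(g, g.length - remaining, g.length))
    return shapely.unary_union(pieces)


def extract_reach_forage(
    reach_geom,
    reaches_df: pd.DataFrame,
    bfi: RasterGrid,
    distance: float,
    channel_half_width: float = 0.0,
) -> float:
    """Top-50% mean BFI in the search area ``distance`` metres from the bank.

    The search area is the reach extended 100 m up- and downstream along the
    network (truncated at headwaters/outlet), buffered by the channel
    half-width plus ``distance``. Returns 0 (with a warning) if no cell
    centre falls inside.
    """
    extended = _extend_along_network(reach_geom, reaches_df, 100.0)
    buf = extended.buffer(channel_half_width + distance)
    xs, ys = bfi.cell_centers()
    xmin, ymin, xmax, ymax = buf.bounds
    ci = np.where((xs >= xmin - bfi.cell_size) & (xs <= xmax + bfi.cell_size))[0]
    ri = np.where((ys >= ymin - bfi.cell_size) & (ys <= ymax + bfi.cell_size))[0]
    if len(ci) == 0 or len(ri) == 0:
        warnings.warn("empty forage search area; returning 0")
        return 0.0
    xx, yy = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.intersects_xy(buf, xx.ravel(), yy.ravel()).reshape(xx.shape)
    vals = bfi.data[np.ix_(ri, ci)][inside]
    vals = vals[vals != bfi.nodata]
    if vals.size == 0:
        warnings.warn("empty forage search area; returning 0")
        return 0.0
    return top_half_mean(vals)


BFI_CATEGORIES = ["unsuitable", "low", "medium", "high", "preferred"]


def classify_bfi_category(riparian_bfi):
    """BFI class from the riparian summary: unsuitable (<=1), low (<=2),
    medium (<=3), high (<=4), preferred (<=5)."""
    v = np.atleast_1d(np.asarray(riparian_bfi, dtype=float))
    if np.any((v < 0) | (v > 5)):
        raise ValueError("riparian BFI outside [0, 5]")
    idx = np.clip(np.ceil(v).astype(int) - 1, 0, 4)
    return np.array(BFI_CATEGORIES, dtype=object)[idx]
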