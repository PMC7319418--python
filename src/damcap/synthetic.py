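"""Synthetic catchments with known generative parameters.

Everything the pipeline consumes — terrain, stream network, channel
polygons, four landcover sources, gauge flow series and beaver observations
— can be generated here so each downstream stage is testable without
national datasets. Terrain is constructed (a valley composition draped
around a hand-built channel tree), not simulated: channels descend strictly
monotonically, hillslopes rise away from them, and all outputs are
bit-identical for identical seeds.

The observation simulator is the single source of "truth" parameters
(activity logits per forage category; zero-inflated negative binomial
damming coefficients) and serialises them beside its outputs so recovery
tests can compare estimates against the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.ops
from scipy.spatial import cKDTree
from scipy.special import expit
from shapely.geometry import LineString

from .forage import BFI_CATEGORIES, load_suitability_tables
from .grid import RasterGrid

DEFAULT_MOSAIC = [
    ("Broadleaf woodland", "os_vector", 0.40),
    ("Unimproved grass", "os_vector", 0.25),
    ("Coniferous woodland", "os_vector", 0.15),
    ("3", "lcm_raster", 0.30),
    ("1", "lcm_raster", 0.45),
    ("2", "lcm_raster", 0.25),
    ("Woody linear feature", "wlff_vector", 0.20),
]

# Monotone activity logits per forage category (unsuitable .. preferred):
# active probabilities ~ [0.05, 0.18, 0.27, 0.38, 0.73]
DEFAULT_ACTIVITY_LOGITS = (-3.0, -1.5, -1.0, -0.5, 1.0)

# Damming truth: zero-inflation logit pi = g0 + g1 * max_dams,
# count log mu = b0 + b1 * max_dams, NB2 dispersion alpha.
DEFAULT_DAMMING = {"g0": 1.0, "g1": -0.9, "b0": -1.2, "b1": 0.55, "alpha": 0.6}


@dataclass
class CatchmentScenario:
    """Generative parameters for one synthetic catchment."""

    grid_shape: tuple[int, int] = (64, 64)
    cell_size: float = 5.0
    relief: float = 60.0
    drainage_style: str = "dendritic_synthetic"
    tributaries: int = 3
    landcover_mosaic: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_MOSAIC)
    )
    lcm_background: str | None = "1"
    gauge_count: int = 4
    flow_law: tuple[float, float] = (0.05, 0.8)  # Q = a * Area_km2 ** b
    flow_sigma: float = 0.3
    n_days: int = 730
    activity_logits: tuple[float, ...] = DEFAULT_ACTIVITY_LOGITS
    damming: dict = field(default_factory=lambda: dict(DEFAULT_DAMMING))
    seed: int = 1

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small; need at least 16x16")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.gauge_count < 2:
            raise ValueError("need at least two gauges")
        if self.flow_law[0] <= 0 or self.flow_law[1] <= 0:
            raise ValueError("flow-law parameters must be positive")
        if self.drainage_style not in ("dendritic_synthetic", "single_valley"):
            raise ValueError(f"unknown drainage style {self.drainage_style!r}")
        per_source: dict[str, float] = {}
        for _, src, frac in self.landcover_mosaic:
            per_source[src] = per_source.get(src, 0.0) + frac
        for src, tot in per_source.items():
            if tot > 1.0 + 1e-9:
                raise ValueError(f"mosaic fractions for {src} sum to {tot:.2f} > 1")
        if len(self.activity_logits) != len(BFI_CATEGORIES):
            raise ValueError("one activity logit per forage category required")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticTerrain:
    dtm: RasterGrid
    network: pd.DataFrame  # geometry column of noded polylines
    channels: shapely.geometry.base.BaseGeometry  # channel-area polygons
    outlet_xy: tuple[float, float]


def _cellxy(scenario: CatchmentScenario, row: float, col: float) -> tuple[float, float]:
    nrows, _ = scenario.grid_shape
    cs = scenario.cell_size
    return ((col + 0.5) * cs, (nrows - row - 0.5) * cs)


def _build_network(scenario: CatchmentScenario) -> list[LineString]:
    nrows, ncols = scenario.grid_shape
    cx = ncols // 2
    top = 3
    bottom = nrows - 1
    if scenario.drainage_style == "single_valley":
        pts = [_cellxy(scenario, r, cx) for r in range(top, bottom + 1)]
        return [LineString(pts)]
    # dendritic: a main stem with perpendicular (purely horizontal)
    # tributaries, which rasterise to clean one-cell-wide chains with no
    # corner cells for D8 to shortcut
    k = scenario.tributaries
    junction_rows = np.linspace(top + 8, bottom - 6, k).round().astype(int)
    lines = []
    prev = top
    for i, jr in enumerate(junction_rows):
        stem = [_cellxy(scenario, r, cx) for r in range(prev, jr + 1)]
        lines.append(LineString(stem))
        side = 1 if i % 2 == 0 else -1
        reach_cols = cx - 3 if side < 0 else ncols - cx - 4
        length = int(min(8 + 2 * i, reach_cols))
        trib = [
            _cellxy(scenario, jr, cx + side * step) for step in range(length, 0, -1)
        ] + [_cellxy(scenario, jr, cx)]
        lines.append(LineString(trib))
        prev = jr
    lines.append(LineString([_cellxy(scenario, r, cx) for r in range(prev, bottom + 1)]))
    return lines


def generate_terrain(scenario: CatchmentScenario) -> SyntheticTerrain:
    """Construct the DTM, stream network and channel polygons.

    Channel vertex elevations decrease strictly from head to outlet;
    hillslope cells sit above the nearest channel point, rising with
    distance, so D8 routing on the burned DTM follows the mapped network.
    """
    lines = _build_network(scenario)
    outlet = lines[-1].coords[-1]

    # along-network distance to the outlet for every channel vertex
    # (vertices are spaced one cell apart by construction)
    tree_pts, tree_d, dist_lut = _network_distances(lines, outlet)
    kd = cKDTree(tree_pts)

    nrows, ncols = scenario.grid_shape
    cs = scenario.cell_size
    xs = (np.arange(ncols) + 0.5) * cs
    ys = (nrows - np.arange(nrows) - 0.5) * cs
    xx, yy = np.meshgrid(xs, ys)
    d, idx = kd.query(np.column_stack([xx.ravel(), yy.ravel()]))
    dmax = tree_d.max()
    channel_z = scenario.relief * 0.45 * tree_d / max(dmax, 1e-9)
    z = channel_z[idx] + 0.08 * d + scenario.relief * 0.55 * (d / (ncols * cs / 2)) ** 2
    dtm = RasterGrid(
        z.reshape(nrows, ncols), x_origin=0.0, y_origin=nrows * cs, cell_size=cs
    )

    # channel polygons: each segment buffered by a width growing downstream
    pieces = []
    for line in lines:
        coords = list(line.coords)
        for a, b in zip(coords, coords[1:]):
            d_here = dist_lut[tuple(np.round(a, 6))]
            width = 1.0 + 5.0 * (1.0 - d_here / max(dmax, 1e-9))
            pieces.append(LineString([a, b]).buffer(width / 2))
    channels = shapely.unary_union(pieces)

    network = pd.DataFrame({"geometry": lines})
    return SyntheticTerrain(dtm=dtm, network=network, channels=channels, outlet_xy=outlet)


def _network_distances(lines, outlet):
    """Channel vertices, their along-network distance to the outlet, and the
    lookup table keyed by rounded coordinates."""
    import networkx as nx

    g = nx.Graph()
    for line in lines:
        coords = list(line.coords)
        for a, b in zip(coords, coords[1:]):
            g.add_edge(
                tuple(np.round(a, 6)),
                tuple(np.round(b, 6)),
                weight=float(np.hypot(b[0] - a[0], b[1] - a[1])),
            )
    dist = nx.single_source_dijkstra_path_length(g, tuple(np.round(outlet, 6)))
    pts = np.array(list(dist.keys()))
    d = np.array(list(dist.values()))
    return pts, d, dist


# --- landcover ---------------------------------------------------------------


def _corridor_chunks(network: pd.DataFrame, chunk_m: float = 50.0):
    chunks = []
    for geom in network["geometry"]:
        n = max(int(np.ceil(geom.length / chunk_m)), 1)
        cuts = np.linspace(0, geom.length, n + 1)
        for i in range(n):
            chunks.append(shapely.ops.substring(geom, cuts[i], cuts[i + 1]))
    return chunks


def generate_landcover(
    scenario: CatchmentScenario, network: pd.DataFrame, template: RasterGrid
) -> dict:
    """Generate the landcover sources named in the scenario's mosaic.

    Riparian 50 m chunks of the network corridor are allocated to class
    labels proportionally to the target fractions (seeded shuffle), giving
    categorical vector polygons (``os_vector``), a categorical raster over
    the corridor on an optional background class (``lcm_raster``), hedgerow
    offset lines (``wlff_vector``) and a 20 m percent tree-cover raster
    (``tcd_raster``, drawn uniform(0, 100) everywhere).
    """
    tables = load_suitability_tables()
    for label, src, _ in scenario.landcover_mosaic:
        if src not in tables:
            raise KeyError(f"unknown landcover source {src!r}")
        t = tables[src]
        if t.classes is not None and label not in t.classes and t.default is None:
            raise KeyError(f"class {label!r} not in suitability table for {src}")

    rng = scenario.rng(stream=2)
    chunks = _corridor_chunks(network)
    sources: dict[str, object] = {}
    by_source: dict[str, list[tuple[str, float]]] = {}
    for label, src, frac in scenario.landcover_mosaic:
        by_source.setdefault(src, []).append((label, frac))

    for src, entries in by_source.items():
        order = rng.permutation(len(chunks))
        n = len(chunks)
        counts = [int(round(f * n)) for _, f in entries]
        start = 0
        assignments: list[tuple[int, str]] = []
        for (label, _), cnt in zip(entries, counts):
            assignments.extend((order[i], label) for i in range(start, min(start + cnt, n)))
            start += cnt
        if src in ("os_vector", "lcm_vector"):
            rows = [
                {"geometry": chunks[i].buffer(40.0), "landclass": label}
                for i, label in assignments
            ]
            sources[src] = pd.DataFrame(rows, columns=["geometry", "landclass"])
        elif src == "wlff_vector":
            rows = []
            for i, label in assignments:
                off = chunks[i].offset_curve(20.0)
                if not off.is_empty:
                    rows.append({"geometry": off, "landclass": label})
            sources[src] = pd.DataFrame(rows, columns=["geometry", "landclass"])
        elif src == "lcm_raster":
            bg = scenario.lcm_background
            data = np.full(template.shape, float(bg) if bg is not None else template.nodata)
            grid = RasterGrid(
                data, template.x_origin, template.y_origin, template.cell_size, template.nodata
            )
            for i, label in assignments:
                poly = chunks[i].buffer(40.0)
                _fill_cells_in_polygon(grid, poly, float(label))
            sources[src] = grid
        else:
            raise KeyError(f"generator does not know how to build source {src!r}")

    if "tcd_raster" not in sources:
        cs = 20.0
        nrows = int(np.ceil(template.shape[0] * template.cell_size / cs))
        ncols = int(np.ceil(template.shape[1] * template.cell_size / cs))
        tcd = rng.uniform(0.0, 100.0, size=(nrows, ncols))
        sources["tcd_raster"] = RasterGrid(
            tcd, template.x_origin, template.y_origin, cell_size=cs
        )
    return sources


def _fill_cells_in_polygon(grid: RasterGrid, poly, value: float) -> None:
    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = poly.bounds
    ci = np.where((xs >= xmin) & (xs <= xmax))[0]
    ri = np.where((ys >= ymin) & (ys <= ymax))[0]
    if len(ci) == 0 or len(ri) == 0:
        return
    xx, yy = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    sub = grid.data[np.ix_(ri, ci)]
    sub[inside] = value
    grid.data[np.ix_(ri, ci)] = sub


# --- gauges ------------------------------------------------------------------


def generate_flows(
    scenario: CatchmentScenario, network: pd.DataFrame, flow_grid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily gauge flows (lognormal about a * Area**b) and gauge metadata.

    Gauges sit on the main stem; each gauge's catchment area is read from
    the flow-accumulation grid at its cell, so the rating-curve stage sees
    exactly the areas the terrain stage would assign.
    """
    a, b = scenario.flow_law
    rng = scenario.rng(stream=3)
    stem = max(network["geometry"], key=lambda g: g.length)
    fracs = np.linspace(0.25, 0.95, scenario.gauge_count)
    rows_flow, rows_meta = [], []
    dates = pd.date_range("2015-01-01", periods=scenario.n_days, freq="D")
    for i, f in enumerate(fracs):
        pt = stem.interpolate(f * stem.length)
        r, c = flow_grid.burned.xy_to_rowcol(pt.x, pt.y)
        area_km2 = float(flow_grid.accumulation[int(r), int(c)]) * flow_grid.cell_size**2 / 1e6
        q_mean = a * area_km2**b
        eps = rng.standard_normal(scenario.n_days) if scenario.flow_sigma > 0 else 0.0
        flows = q_mean * np.exp(scenario.flow_sigma * eps)
        gid = f"G{i:02d}"
        rows_meta.append({"gauge_id": gid, "area_km2": area_km2, "x": pt.x, "y": pt.y})
        rows_flow.append(
            pd.DataFrame({"date": dates, "flow_m3s": np.broadcast_to(flows, (scenario.n_days,)), "gauge_id": gid})
        )
    return pd.concat(rows_flow, ignore_index=True), pd.DataFrame(rows_meta)


# --- observations ------------------------------------------------------------


def simulate_observations(
    scenario: CatchmentScenario, reaches: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Sample feeding signs and dams from the occupancy truth model.

    Activity is Bernoulli with a logit per forage category of the riparian
    BFI; dams on active reaches follow a zero-inflated negative binomial
    whose linear predictors use the modelled maximum dams per reach. Points
    are placed on the reach geometry. Returns (points, truth parameters).
    """
    rng = scenario.rng(stream=4)
    logits = dict(zip(BFI_CATEGORIES, scenario.activity_logits))
    dm = scenario.damming
    rows = []
    for rec in reaches.itertuples():
        p_active = float(expit(logits[rec.bfi_category]))
        if rng.random() >= p_active:
            continue
        geom = rec.geometry
        rows.append(
            {"geometry": geom.interpolate(rng.uniform(0, geom.length)), "kind": "feeding_sign"}
        )
        x = rec.max_dams
        pi = float(expit(dm["g0"] + dm["g1"] * x))
        if rng.random() < pi:
            n_dams = 0
        else:
            mu = np.exp(dm["b0"] + dm["b1"] * x)
            n_dams = rng.negative_binomial(1.0 / dm["alpha"], 1.0 / (1.0 + dm["alpha"] * mu))
        for _ in range(int(n_dams)):
            rows.append(
                {"geometry": geom.interpolate(rng.uniform(0, geom.length)), "kind": "dam"}
            )
    points = pd.DataFrame(rows, columns=["geometry", "kind"])
    truth = {
        "activity_logits": dict(zip(BFI_CATEGORIES, scenario.activity_logits)),
        "damming": dict(dm),
        "seed": scenario.seed,
    }
    return points, truth


def simulate_reach_table(
    n_reaches: int,
    seed: int,
    damming: dict | None = None,
    max_dams_shape: float = 1.5,
    max_dams_scale: float = 1.0,
) -> pd.DataFrame:
    """Active-reach table for the count model at survey-like scale.

    Draws modelled max dams per reach from a Gamma distribution (most
    reaches can hold under two dams, a tail can hold more) and samples
    observed dams from the zero-inflated negative binomial truth. Returns
    columns reach_id, max_dams, observed_dams, is_active (all True).
    """
    dm = dict(DEFAULT_DAMMING if damming is None else damming)
    rng = np.random.default_rng(seed)
    x = rng.gamma(max_dams_shape, max_dams_scale, n_reaches).clip(0.0, 6.0)
    pi = expit(dm["g0"] + dm["g1"] * x)
    mu = np.exp(dm["b0"] + dm["b1"] * x)
    y = rng.negative_binomial(1.0 / dm["alpha"], 1.0 / (1.0 + dm["alpha"] * mu))
    y[rng.random(n_reaches) < pi] = 0
    return pd.DataFrame(
        {
            "reach_id": np.arange(n_reaches),
            "max_dams": x,
            "observed_dams": y.astype(int),
            "is_active": True,
        }
    )


def write_truth_sidecar(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
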