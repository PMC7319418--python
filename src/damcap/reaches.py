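"""Working reaches: segmentation, bankfull width, observation snapping.

The stream network, already noded at confluences, is cut into working
reaches under 200 m (longer features are split into the minimum number of
equal parts). Reaches carry the attributes the capacity model needs; beaver
field observations (feeding signs, dams, removed dams) are snapped to the
nearest reach to flag activity and count dams.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.ops import substring

log = logging.getLogger(__name__)

MAX_REACH_M = 200.0


def segment_network(network_geoms) -> pd.DataFrame:
    """Split polylines into reaches < 200 m.

    Features under 200 m pass through; features of 200 m or more are split
    into equal parts (a feature of exactly 200 m is split in two). Total
    length is conserved. Zero-length features are dropped with a warning.
    """
    rows = []
    for geom in network_geoms:
        if geom.length <= 0:
            warnings.warn("zero-length feature dropped")
            continue
        if geom.length < MAX_REACH_M:
            parts = [geom]
        else:
            n = int(np.ceil(geom.length / MAX_REACH_M))
            if geom.length / n >= MAX_REACH_M:
                n += 1
            cuts = np.linspace(0.0, geom.length, n + 1)
            parts = [substring(geom, cuts[i], cuts[i + 1]) for i in range(n)]
        rows.extend(parts)
    df = pd.DataFrame(
        {
            "reach_id": np.arange(len(rows)),
            "geometry": rows,
            "length_m": [g.length for g in rows],
        }
    )
    return df


def mean_bankfull_width(
    reach_geom, channel_polygons, buffer_m: float = 20.0, min_width_m: float = 0.5
) -> tuple[float, bool]:
    """Channel-polygon area within a 20 m reach buffer, divided by length.

    Returns (width, capped): reaches with no intersecting channel polygon get
    the declared minimum width; ``capped`` flags channels wider than the
    buffer can measure (clip touches the buffer boundary).
    """
    buf = reach_geom.buffer(buffer_m, cap_style="flat")
    clipped = buf.intersection(channel_polygons) if channel_polygons is not None else None
    if clipped is None or clipped.is_empty:
        return min_width_m, False
    width = clipped.area / reach_geom.length
    # the 20 m buffer caps measurable width at ~2 x buffer
    capped = channel_polygons.buffer(-buffer_m * 0.999).intersects(reach_geom)
    return width, capped


def snap_observations(
    points_df: pd.DataFrame, reaches_df: pd.DataFrame, exclusion_masks=None
) -> pd.DataFrame:
    """Assign each observation to the nearest reach by perpendicular distance.

    Points inside any exclusion polygon are dropped (their count is recorded
    in ``df.attrs['excluded']``). Equidistant points take the lowest
    reach_id (logged). Distances over 100 m are logged as warnings; there is
    no maximum snap distance.
    """
    if len(reaches_df) == 0:
        raise ValueError("no reaches to snap to")
    geoms = list(reaches_df["geometry"])
    ids = reaches_df["reach_id"].to_numpy()
    rows = []
    excluded = 0
    for _, rec in points_df.iterrows():
        pt = rec["geometry"]
        if exclusion_masks is not None and any(m.intersects(pt) for m in exclusion_masks):
            excluded += 1
            continue
        dists = np.array([g.distance(pt) for g in geoms])
        best = np.min(dists)
        cand = np.flatnonzero(np.isclose(dists, best))
        if len(cand) > 1:
            log.info("tie snapping point to reaches %s; lowest id wins", ids[cand])
        chosen = cand[np.argmin(ids[cand])]
        if best > 100:
            log.warning("observation snapped over %.0f m", best)
        rows.append(
            {
                "geometry": pt,
                "kind": rec["kind"],
                "snapped_reach_id": int(ids[chosen]),
                "snap_distance_m": float(best),
            }
        )
    out = pd.DataFrame(rows, columns=["geometry", "kind", "snapped_reach_id", "snap_distance_m"])
    out.attrs["excluded"] = excluded
    return out


def flag_activity(reaches_df: pd.DataFrame, snapped: pd.DataFrame) -> pd.DataFrame:
    """Mark active reaches and count observed dams.

    A reach is active iff at least one observation of any kind snapped to it.
    ``observed_dams`` counts dam points only; removed/collapsed dams count
    toward activity but not toward the dam totals.
    """
    out = reaches_df.copy()
    active_ids = set(snapped["snapped_reach_id"]) if len(snapped) else set()
    out["is_active"] = out["reach_id"].isin(active_ids)
    dam_counts = (
        snapped[snapped["kind"] == "dam"].groupby("snapped_reach_id").size()
        if len(snapped)
        else pd.Series(dtype=int)
    )
    out["observed_dams"] = out["reach_id"].map(dam_counts).fillna(0).astype(int)
    return out
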