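"""Hourly land-avoiding interpolated paths and region-use metrics.

Between consecutive detections at different stations the fish is placed
along the straight segment when it stays in water, otherwise along the
shortest path in an 8-connected raster graph over water cells.  Hourly
positions are spaced proportionally to elapsed time along the route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString

__all__ = [
    "WaterGraph",
    "water_graph",
    "interpolate_path",
    "occupancy",
    "compress_for_beta",
    "OccupancySummary",
]


@dataclass
class WaterGraph:
    """8-connected grid graph over water cells."""

    graph: nx.Graph
    resolution: float
    origin: tuple  # (minx, miny)
    shape: tuple  # (ncol, nrow)

    def node_of(self, x: float, y: float):
        """Nearest water node to (x, y)."""
        col = int(round((x - self.origin[0]) / self.resolution - 0.5))
        row = int(round((y - self.origin[1]) / self.resolution - 0.5))
        if (col, row) in self.graph:
            return (col, row)
        # spiral outwards for shore-adjacent points
        for radius in range(1, max(self.shape) + 1):
            best, best_d = None, np.inf
            for dc in range(-radius, radius + 1):
                for dr in range(-radius, radius + 1):
                    if max(abs(dc), abs(dr)) != radius:
                        continue
                    cand = (col + dc, row + dr)
                    if cand in self.graph:
                        cx, cy = self.xy_of(cand)
                        d = (cx - x) ** 2 + (cy - y) ** 2
                        if d < best_d:
                            best, best_d = cand, d
            if best is not None:
                return best
        raise ValueError("no water node anywhere near point")

    def xy_of(self, node) -> tuple:
        col, row = node
        return (
            self.origin[0] + (col + 0.5) * self.resolution,
            self.origin[1] + (row + 0.5) * self.resolution,
        )

    def shortest_path_xy(self, a_xy, b_xy) -> np.ndarray:
        """Polyline (k, 2) from a to b through the water graph."""
        na, nb = self.node_of(*a_xy), self.node_of(*b_xy)
        nodes = nx.shortest_path(self.graph, na, nb, weight="weight")
        mid = np.array([self.xy_of(n) for n in nodes])
        return np.vstack([np.asarray(a_xy)[None, :], mid, np.asarray(b_xy)[None, :]])


def water_graph(lake, resolution_m: float = 250.0) -> WaterGraph:
    """Build the raster water graph; deterministic given inputs.

    Raises when the water cells split into disconnected components (the
    narrow-passage resolution precondition is then violated).
    """
    if resolution_m <= 0:
        raise ValueError("resolution must be positive")
    minx, miny, maxx, maxy = lake.water.bounds
    ncol = int(np.ceil((maxx - minx) / resolution_m))
    nrow = int(np.ceil((maxy - miny) / resolution_m))
    xs = minx + (np.arange(ncol) + 0.5) * resolution_m
    ys = miny + (np.arange(nrow) + 0.5) * resolution_m
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    wet = shapely.contains_xy(lake.water, gx.ravel(), gy.ravel()).reshape(ncol, nrow)

    g = nx.Graph()
    cols, rows = np.nonzero(wet)
    g.add_nodes_from(zip(cols.tolist(), rows.tolist()))
    diag = np.sqrt(2.0) * resolution_m
    for (dc, dr), w in {
        (1, 0): resolution_m,
        (0, 1): resolution_m,
        (1, 1): diag,
        (1, -1): diag,
    }.items():
        c2, r2 = cols + dc, rows + dr
        ok = (c2 >= 0) & (c2 < ncol) & (r2 >= 0) & (r2 < nrow)
        ok[ok] &= wet[c2[ok], r2[ok]]
        g.add_weighted_edges_from(
            zip(
                zip(cols[ok].tolist(), rows[ok].tolist()),
                zip(c2[ok].tolist(), r2[ok].tolist()),
                itertools.repeat(w),
            )
        )
    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise ValueError(
            f"water raster splits into {n_comp} components (sizes {sizes[:5]}); "
            "decrease the resolution"
        )
    return WaterGraph(g, resolution_m, (minx, miny), (ncol, nrow))


def _route(lake, graph: WaterGraph, a_xy, b_xy) -> np.ndarray:
    """Straight segment if fully in water, else graph shortest path."""
    if np.allclose(a_xy, b_xy):
        return np.array([a_xy, b_xy], dtype=float)
    seg = LineString([a_xy, b_xy])
    if lake.water.covers(seg):
        return np.array([a_xy, b_xy], dtype=float)
    return graph.shortest_path_xy(a_xy, b_xy)


def _points_along(polyline: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Positions at arc-length fractions of a polyline."""
    seg = np.diff(polyline, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.r_[0.0, np.cumsum(seglen)]
    total = cum[-1]
    if total == 0:
        return np.repeat(polyline[[0]], len(fractions), axis=0)
    target = np.clip(fractions, 0, 1) * total
    idx = np.clip(np.searchsorted(cum, target, side="right") - 1, 0, len(seglen) - 1)
    t = np.where(seglen[idx] > 0, (target - cum[idx]) / np.maximum(seglen[idx], 1e-12), 0.0)
    return polyline[idx] + seg[idx] * t[:, None]


def interpolate_path(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    lake,
    graph: WaterGraph,
) -> pd.DataFrame:
    """Hourly land-avoiding positions for one fish.

    ``detections`` must belong to a single tag and be time-sorted.
    Returns columns fish, timestamp, x, y, region, interpolated,
    gap_hours (length of the detection gap each point falls in).
    """
    if len(detections) < 2:
        raise ValueError("need at least two detections to interpolate")
    if detections["tag_id"].nunique() > 1:
        raise ValueError("interpolate_path expects a single fish")
    rx = receivers.drop_duplicates("receiver_id").set_index("receiver_id")
    unknown = set(detections["receiver_id"]) - set(rx.index)
    if unknown:
        raise ValueError(f"detections at unknown receivers: {sorted(unknown)}")
    det = detections.sort_values("timestamp", kind="mergesort")
    ts = pd.DatetimeIndex(det["timestamp"])
    if ts.tz is not None:
        ts = ts.tz_localize(None)
    pos = rx.loc[det["receiver_id"], ["x", "y"]].to_numpy(dtype=float)
    station = rx.loc[det["receiver_id"], "station_id"].to_numpy()

    hours = pd.date_range(ts[0].ceil("h"), ts[-1].floor("h"), freq="h")
    if len(hours) == 0:
        return pd.DataFrame(
            columns=["fish", "timestamp", "x", "y", "region", "interpolated", "gap_hours"]
        )
    # index of detection segment each hour falls in
    seg_idx = np.clip(np.searchsorted(ts.to_numpy(), hours.to_numpy(), side="right") - 1, 0, len(ts) - 2)
    out_xy = np.empty((len(hours), 2))
    gap_h = np.empty(len(hours))
    interpolated = np.zeros(len(hours), dtype=bool)

    route_cache: dict = {}
    for i in np.unique(seg_idx):
        sel = seg_idx == i
        t0, t1 = ts[i], ts[i + 1]
        gap = (t1 - t0).total_seconds() / 3600.0
        gap_h[sel] = gap
        if station[i] == station[i + 1] or gap == 0:
            out_xy[sel] = pos[i]
            continue
        key = (station[i], station[i + 1])
        if key not in route_cache:
            route_cache[key] = _route(lake, graph, pos[i], pos[i + 1])
        poly = route_cache[key]
        frac = (
            (hours[sel] - t0).total_seconds() / (t1 - t0).total_seconds()
        )
        out_xy[sel] = _points_along(poly, np.asarray(frac))
        interpolated[sel] = True

    region = lake.region_of_many(out_xy)
    # boundary/land fallbacks: inherit the previous point's region
    for j in range(len(region)):
        if region[j] is None:
            region[j] = region[j - 1] if j > 0 else lake.region_of_many(
                out_xy[[j]] + 1e-6
            )[0]
    return pd.DataFrame(
        {
            "fish": det["tag_id"].iloc[0],
            "timestamp": hours,
            "x": out_xy[:, 0],
            "y": out_xy[:, 1],
            "region": region,
            "interpolated": interpolated,
            "gap_hours": gap_h,
        }
    )


@dataclass
class OccupancySummary:
    fish: str
    season: str
    year: int
    proportions: dict  # region -> proportion of positioned hours
    region_count: int
    max_occupancy: float
    hours: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError("occupancy proportions must sum to 1")


def occupancy(path: pd.DataFrame, calendar, lake) -> list:
    """Per fish-season-instance occupancy summaries from hourly paths."""
    if path.empty:
        return []
    inst = calendar.instance_of_times(path["timestamp"])
    df = path.assign(
        season=inst["label"].to_numpy(), year=inst["year"].to_numpy()
    ).dropna(subset=["season"])
    out = []
    for (fish, season, year), grp in df.groupby(["fish", "season", "year"], sort=False):
        counts = grp["region"].value_counts()
        props = (counts / counts.sum()).to_dict()
        out.append(
            OccupancySummary(
                fish=fish,
                season=season,
                year=int(year),
                proportions=props,
                region_count=int((counts > 0).sum()),
                max_occupancy=float(counts.max() / counts.sum()),
                hours=int(counts.sum()),
            )
        )
    return out


def occupancy_frame(summaries: list) -> pd.DataFrame:
    rows = [
        {
            "fish": s.fish,
            "season": s.season,
            "year": s.year,
            "region_count": s.region_count,
            "max_occupancy": s.max_occupancy,
            "hours": s.hours,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def compress_for_beta(values, n: int) -> np.ndarray:
    """Smithson-Verkuilen compression: y' = (y * (n - 1) + 0.5) / n.

    Maps [0, 1] strictly inside (0, 1); order-preserving; at n = 500 the
    endpoints move by 0.001.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    y = np.asarray(values, dtype=float)
    return (y * (n - 1) + 0.5) / n
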