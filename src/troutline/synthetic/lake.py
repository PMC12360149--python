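"""Synthetic lake geometry: chained basin rectangles, islands, and a
1-km hexagonal grid over water.

All coordinates are planar metres in a local equal-distance projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.ops import unary_union

from ..config import SimConfig

__all__ = ["HexGrid", "LakeGeometry", "make_lake"]


@dataclass
class HexGrid:
    """Hexagonal tiling with flat horizontal edges and 1 cell-spacing
    between adjacent centroids.

    Cells are identified by integer ids assigned row-major over the
    (col, row) lattice; assignment of a point to a cell is by nearest
    centroid (exact for a hexagonal Voronoi tessellation), with ties
    broken toward the lowest cell id.
    """

    spacing: float
    x0: float
    y0: float
    cell_ids: np.ndarray  # (n,) int
    centroids: np.ndarray  # (n, 2) float
    _tree: cKDTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._tree = cKDTree(self.centroids)

    @property
    def circumradius(self) -> float:
        return self.spacing / np.sqrt(3.0)

    def assign(self, xy: np.ndarray) -> np.ndarray:
        """Map points (n, 2) to cell ids; boundary ties -> lowest id."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        k = min(3, len(self.cell_ids))
        dist, idx = self._tree.query(xy, k=k)
        if k == 1:
            return self.cell_ids[np.atleast_1d(idx)]
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        tied = dist - dist[:, [0]] < 1e-9
        out = np.empty(len(xy), dtype=self.cell_ids.dtype)
        for i in range(len(xy)):
            out[i] = self.cell_ids[idx[i][tied[i]]].min()
        return out

    def centroid_of(self, cell_id) -> np.ndarray:
        pos = np.searchsorted(self.cell_ids, cell_id)
        return self.centroids[pos]

    def polygon_of(self, cell_id) -> Polygon:
        cx, cy = self.centroid_of(cell_id)
        r = self.circumradius
        ang = np.deg2rad(np.arange(0, 360, 60))
        return Polygon(np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _hex_lattice(bounds, spacing: float):
    """Centroid lattice covering ``bounds`` with one cell of margin."""
    minx, miny, maxx, maxy = bounds
    r = spacing / np.sqrt(3.0)
    dx = 1.5 * r
    dy = spacing
    ncol = int(np.ceil((maxx - minx) / dx)) + 2
    nrow = int(np.ceil((maxy - miny) / dy)) + 2
    ids, cents = [], []
    next_id = 0
    for col in range(ncol):
        x = minx + col * dx
        off = 0.5 * dy if col % 2 else 0.0
        for row in range(nrow):
            ids.append(next_id)
            cents.append((x, miny + row * dy + off))
            next_id += 1
    return np.asarray(ids), np.asarray(cents, dtype=float)


@dataclass
class LakeGeometry:
    """Regions, land mask, hex grid and per-region depth for one lake."""

    regions: dict  # label -> Polygon
    land: list  # list of Polygon
    region_depth: dict  # label -> depth (m)
    hex: HexGrid
    crs: str = "local-metres"

    def __post_init__(self) -> None:
        self._water = unary_union(list(self.regions.values()))
        if self.land:
            self._water = self._water.difference(unary_union(self.land))
        if self._water.area <= 0:
            raise ValueError("degenerate lake: water area is zero")
        shapely.prepare(self._water)
        self._region_order = list(self.regions)
        for label in self._region_order:
            shapely.prepare(self.regions[label])

    @property
    def water(self):
        return self._water

    @property
    def region_labels(self) -> list:
        return list(self._region_order)

    def contains(self, x: float, y: float) -> bool:
        return bool(shapely.contains_xy(self._water, x, y))

    def contains_many(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return shapely.contains_xy(self._water, xy[:, 0], xy[:, 1])

    def region_of(self, x: float, y: float) -> str | None:
        """Label of the region polygon covering (x, y); None on land.

        Points on a shared boundary go to the region earliest in
        insertion order (deterministic tie-break).
        """
        pt = Point(x, y)
        for label in self._region_order:
            if self.regions[label].covers(pt):
                return label
        return None

    def region_of_many(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        out = np.full(len(xy), None, dtype=object)
        undecided = np.ones(len(xy), dtype=bool)
        for label in self._region_order:
            if not undecided.any():
                break
            hit = undecided & shapely.intersects_xy(
                self.regions[label], xy[:, 0], xy[:, 1]
            )
            out[hit] = label
            undecided &= ~hit
        return out

    def depth_at(self, x: float, y: float) -> float:
        label = self.region_of(x, y)
        if label is None:
            return 0.0
        return self.region_depth[label]

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self, path) -> None:
        feats = []
        for label, poly in self.regions.items():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "region": label,
                        "depth_m": self.region_depth[label],
                    },
                    "geometry": mapping(poly),
                }
            )
        for poly in self.land:
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"land": True},
                    "geometry": mapping(poly),
                }
            )
        doc = {
            "type": "FeatureCollection",
            "features": feats,
            "hex": {"spacing": self.hex.spacing, "x0": self.hex.x0, "y0": self.hex.y0},
            "crs_note": self.crs,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path) -> "LakeGeometry":
        with open(path) as fh:
            doc = json.load(fh)
        regions, depth, land = {}, {}, []
        for feat in doc["features"]:
            props = feat.get("properties", {})
            geom = shape(feat["geometry"])
            if props.get("land"):
                land.append(geom)
            else:
                regions[props["region"]] = geom
                depth[props["region"]] = props.get("depth_m", 0.0)
        hexmeta = doc["hex"]
        return _with_hex_grid(
            regions, land, depth, hexmeta["spacing"], crs=doc.get("crs_note", "")
        )


def _with_hex_grid(regions, land, depth, spacing, crs="local-metres") -> LakeGeometry:
    water = unary_union(list(regions.values()))
    if land:
        water = water.difference(unary_union(land))
    if water.is_empty or water.area <= 0:
        raise ValueError("degenerate lake: water area is zero")
    # full lattice over the bounding box: every water point has a cell,
    # land-centroid cells are simply never the nearest for in-water points
    # far from shore
    ids, cents = _hex_lattice(water.bounds, spacing)
    grid = HexGrid(spacing, water.bounds[0], water.bounds[1], ids, cents)
    return LakeGeometry(regions, land, depth, grid, crs=crs)


def make_lake(config: SimConfig) -> LakeGeometry:
    """Build a lake of rectangular basins chained west to east.

    Each ``(label, width, height, depth)`` entry becomes a rectangle
    sharing its eastern edge with the next basin; rectangles are centred
    on y = 0, so consecutive basins always overlap on a shared edge and
    the water body is connected. Islands are circular land polygons.
    Deterministic given ``config``.
    """
    if not config.regions:
        raise ValueError("config must specify at least one region")
    regions: dict = {}
    depth: dict = {}
    x = 0.0
    for label, width, height, d in config.regions:
        if width <= 0 or height <= 0:
            raise ValueError(f"degenerate extent for region {label!r}")
        regions[label] = box(x, -height / 2.0, x + width, height / 2.0)
        depth[label] = float(d)
        x += width
    land = [
        Point(cx, cy).buffer(radius, quad_segs=16)
        for cx, cy, radius in config.islands
    ]
    return _with_hex_grid(regions, land, depth, config.hex_spacing_m)
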