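"""Known-local-source (KLS) predictors: seven source types x three buffers.

For each grid cell and buffer distance d (default 50/150/300 m from the
cell edge) the features are: road density (km/km^2) for the four road
classes, location density (count/km^2) for food service and gas stations,
and industrial land-use share (area fraction).  The buffer region is the
Euclidean dilation of the 100 m cell square by d (rounded corners), with
closed-form area (s + 2d)^2 - (4 - pi) d^2, and is also the density
denominator — the documented alternative of a fixed 0.01 km^2 denominator
is available via ``denominator="cell"``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import Grid
from .scene import ROAD_CLASSES, POINT_CLASSES

DEFAULT_BUFFERS_M = (50.0, 150.0, 300.0)
KLS_TYPES = ROAD_CLASSES + POINT_CLASSES + ("industrial",)
M2_PER_KM2 = 1e6


def kls_column_names(buffers_m=DEFAULT_BUFFERS_M) -> list[str]:
    """Fixed column order: type-major, buffer-minor — KLS_{type}_{d}."""
    return [f"KLS_{t}_{int(d)}" for t in KLS_TYPES for d in buffers_m]


def buffer_region(cell_polygon, d_m: float):
    """Euclidean dilation of the cell by d_m (rounded corners)."""
    if d_m < 0:
        raise ValueError("buffer distance must be non-negative")
    if d_m == 0:
        return cell_polygon
    return cell_polygon.buffer(d_m, quad_segs=32)


def buffer_area_km2(cell_size_m: float, d_m: float) -> float:
    """Closed-form dilation area in km^2: (s+2d)^2 - (4-pi) d^2."""
    s, d = cell_size_m / 1000.0, d_m / 1000.0
    return (s + 2 * d) ** 2 - (4.0 - math.pi) * d * d


def road_density(lines, cell_polygon, d_m: float, denominator_km2=None) -> float:
    """km of road (clipped to the buffer) per km^2 of buffer area."""
    buf = buffer_region(cell_polygon, d_m)
    if denominator_km2 is None:
        denominator_km2 = buf.area / M2_PER_KM2
    length_km = sum(buf.intersection(ln).length for ln in lines) / 1000.0
    return length_km / denominator_km2


def point_density(points, cell_polygon, d_m: float, denominator_km2=None) -> float:
    """Locations inside the buffer per km^2 of buffer area."""
    buf = buffer_region(cell_polygon, d_m)
    if denominator_km2 is None:
        denominator_km2 = buf.area / M2_PER_KM2
    n = sum(1 for p in points if buf.intersects(p))
    return n / denominator_km2


def industrial_share(polys, cell_polygon, d_m: float, denominator_km2=None) -> float:
    """Fraction of the buffer covered by industrial land (polygons unioned)."""
    buf = buffer_region(cell_polygon, d_m)
    if denominator_km2 is None:
        denominator_km2 = buf.area / M2_PER_KM2
    if not polys:
        return 0.0
    merged = unary_union(list(polys))
    return (buf.intersection(merged).area / M2_PER_KM2) / denominator_km2


def build_feature_matrix(
    layers: dict,
    grid: Grid,
    cell_ids=None,
    buffers_m=DEFAULT_BUFFERS_M,
    denominator: str = "buffer",
) -> pd.DataFrame:
    """Cells x 21 KLS feature matrix with stable column names.

    ``layers`` maps the seven type names to geometry lists (a missing or
    empty layer yields a zero column with a warning).  ``denominator`` is
    ``"buffer"`` (dilated-region area, default) or ``"cell"`` (fixed cell
    area).  Rows are indexed by cell id in ascending order, matching the
    per-cell record table.
    """
    if denominator not in ("buffer", "cell"):
        raise ValueError("denominator must be 'buffer' or 'cell'")
    if cell_ids is None:
        cell_ids = grid.cell_ids()
    cell_ids = np.asarray(cell_ids)
    x, y = grid.cell_origin(cell_ids)
    s = grid.cell_size
    cells = shapely.box(x, y, x + s, y + s)

    # union industrial once; index roads/points with an STRtree per layer
    prepared = {}
    for t in KLS_TYPES:
        geoms = list(layers.get(t, []) or [])
        if not geoms:
            warnings.warn(f"KLS layer {t!r} absent or empty; zero column emitted")
            prepared[t] = None
        elif t == "industrial":
            prepared[t] = unary_union(geoms)
        else:
            prepared[t] = STRtree(geoms)

    out = pd.DataFrame(
        0.0, index=pd.Index(cell_ids, name="cell_id"), columns=kls_column_names(buffers_m)
    )
    cell_area_km2 = (s / 1000.0) ** 2
    for d in buffers_m:
        bufs = shapely.buffer(cells, d, quad_segs=32) if d > 0 else cells
        if denominator == "buffer":
            denom = shapely.area(bufs) / M2_PER_KM2
        else:
            denom = np.full(len(cell_ids), cell_area_km2)
        for t in KLS_TYPES:
            col = f"KLS_{t}_{int(d)}"
            obj = prepared[t]
            if obj is None:
                continue
            vals = np.zeros(len(cell_ids))
            if t == "industrial":
                inter = shapely.intersection(bufs, obj)
                vals = (shapely.area(inter) / M2_PER_KM2) / denom
            elif t in POINT_CLASSES:
                ci, _ = obj.query(bufs, predicate="intersects")
                cnt = np.bincount(ci, minlength=len(cell_ids))
                vals = cnt / denom
            else:  # road classes
                ci, gi = obj.query(bufs, predicate="intersects")
                if len(ci):
                    geoms = np.asarray(obj.geometries, dtype=object)[gi]
                    lens = shapely.length(shapely.intersection(bufs[ci], geoms)) / 1000.0
                    total = np.bincount(ci, weights=lens, minlength=len(cell_ids))
                    vals = total / denom
            out[col] = vals
    return out


def sparsity_report(features: pd.DataFrame) -> pd.Series:
    """Per-column fraction of cells with exactly zero density."""
    return (features == 0).mean()


OSM_TAG_MAP = {
    # OSM-style tag -> KLS class; the importer's default mapping
    ("highway", "residential"): "residential",
    ("highway", "primary"): "arterial",
    ("highway", "secondary"): "arterial",
    ("highway", "motorway"): "highway",
    ("highway", "motorway_link"): "on_ramp",
    ("amenity", "restaurant"): "food_service",
    ("amenity", "fast_food"): "food_service",
    ("amenity", "cafe"): "food_service",
    ("amenity", "fuel"): "gas_stations",
    ("landuse", "industrial"): "industrial",
}


def classify_osm_tags(tags: dict, tag_map: dict = None) -> str | None:
    """Map an OSM-style tag dict to one of the seven KLS classes (or None)."""
    tag_map = OSM_TAG_MAP if tag_map is None else tag_map
    for (key, value), cls in tag_map.items():
        if tags.get(key) == value:
            return cls
    return None


def synthetic_kls_matrix(n: int, seed: int = 0) -> pd.DataFrame:
    """A 21-column KLS-like design matrix without scene geometry.

    For simulation studies that need the statistical shape of the feature
    matrix — zero inflation of sparse source types, strong (but not
    deterministic) correlation among the three buffer columns of a family —
    while keeping each column's effect identifiable.  Each family draws a
    latent distance-to-source per row; the buffer-d column is
    (R_d - z) * lognormal noise where the source is within reach (z < R_d),
    else 0, so presence is nested across buffers but values are not exact
    transforms of one another (a single straight source line in real
    geometry *does* make them deterministic transforms, which defeats
    column-level recovery tests).
    """
    rng = np.random.default_rng(seed)
    # typical latent distance scale per family, meters; larger = sparser
    scale = {
        "residential": 120.0, "arterial": 300.0, "highway": 900.0,
        "on_ramp": 1200.0, "food_service": 500.0, "gas_stations": 700.0,
        "industrial": 1000.0,
    }
    cols = {}
    for fam in KLS_TYPES:
        z = rng.exponential(scale[fam], n)
        for d in (50.0, 150.0, 300.0):
            reach = z < d + 50.0  # cell-edge offset
            eps = np.exp(rng.normal(0.0, 0.5, n))
            cols[f"KLS_{fam}_{int(d)}"] = np.where(reach, (d + 50.0 - z) * eps / 100.0, 0.0)
    return pd.DataFrame(cols)[kls_column_names()]
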