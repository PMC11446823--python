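"""Plain-text file plumbing: GeoJSON vector layers, CSV tables, YAML config.

Geometry layers are written as GeoJSON FeatureCollections in planar
projected meters (no CRS member is emitted).  Scene serialization writes
one GeoJSON file per layer, a block-group GeoJSON carrying attributes, the
truth table as CSV and the config as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .grid import Grid
from .scene import ROAD_CLASSES, Scene, SceneConfig


def write_geojson(path, geometries, properties=None):
    """Write geometries (+ optional per-feature property dicts) as GeoJSON."""
    feats = []
    for i, geom in enumerate(geometries):
        props = properties[i] if properties is not None else {}
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}), encoding="utf-8"
    )


def read_geojson(path) -> tuple[list, list]:
    """Read a GeoJSON FeatureCollection -> (geometries, property dicts)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    geoms, props = [], []
    for f in data["features"]:
        geoms.append(shape(f["geometry"]))
        props.append(f.get("properties") or {})
    return geoms, props


def write_block_groups(path, block_groups: pd.DataFrame):
    cols = [c for c in block_groups.columns if c != "geometry"]
    props = block_groups[cols].to_dict("records")
    write_geojson(path, list(block_groups.geometry), props)


def read_block_groups(path) -> pd.DataFrame:
    geoms, props = read_geojson(path)
    df = pd.DataFrame(props)
    df["geometry"] = geoms
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_config(path, config: SceneConfig):
    Path(path).write_text(
        yaml.safe_dump(_jsonable(dataclasses.asdict(config))), encoding="utf-8"
    )


def read_config(path) -> SceneConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if "base_shares" in data:
        data["base_shares"] = tuple(data["base_shares"])
    return SceneConfig(**data)


def write_grid(path, grid: Grid):
    data = {
        "x0": grid.x0, "y0": grid.y0, "ncols": grid.ncols, "nrows": grid.nrows,
        "cell_size": grid.cell_size,
        "active_cells": [int(i) for i in grid.cell_ids()],
    }
    Path(path).write_text(json.dumps(data), encoding="utf-8")


def read_grid(path) -> Grid:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    active = np.zeros(data["nrows"] * data["ncols"], dtype=bool)
    active[data["active_cells"]] = True
    return Grid(
        data["x0"], data["y0"], data["ncols"], data["nrows"], data["cell_size"],
        active.reshape(data["nrows"], data["ncols"]),
    )


def write_scene(outdir, scene: Scene):
    """Serialize a scene: GeoJSON layers, block groups, grid, truth CSV, config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, geoms in scene.layers().items():
        write_geojson(outdir / f"{name}.geojson", geoms)
    write_block_groups(outdir / "block_groups.geojson", scene.block_groups)
    write_grid(outdir / "grid.json", scene.grid)
    if scene.truth is not None:
        scene.truth.to_csv(outdir / "truth.csv")
    write_config(outdir / "scene_config.yaml", scene.config)


def read_scene(outdir) -> Scene:
    outdir = Path(outdir)
    config = read_config(outdir / "scene_config.yaml")
    grid = read_grid(outdir / "grid.json")
    roads = {}
    for cls in ROAD_CLASSES:
        roads[cls], _ = read_geojson(outdir / f"{cls}.geojson")
    food, _ = read_geojson(outdir / "food_service.geojson")
    gas, _ = read_geojson(outdir / "gas_stations.geojson")
    industrial, _ = read_geojson(outdir / "industrial.geojson")
    bgs = read_block_groups(outdir / "block_groups.geojson")
    truth_path = outdir / "truth.csv"
    truth = pd.read_csv(truth_path, index_col="cell_id") if truth_path.exists() else None
    return Scene(
        config=config, grid=grid, roads=roads, food_service=food,
        gas_stations=gas, industrial=industrial, block_groups=bgs, truth=truth,
    )


def write_traces(path, traces: pd.DataFrame):
    traces.to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["t"])
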