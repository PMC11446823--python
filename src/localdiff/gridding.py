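"""Reduce 1 Hz mobile-monitoring streams to per-cell concentration estimates.

Protocol: each on-road point is assigned to a unique 100 m grid cell
(half-open edges); within a cell, timestamps are examined to isolate
individual drive passes (maximal runs of points whose consecutive gaps stay
at or below a gap threshold); each pass contributes its arithmetic mean;
the cell's long-term estimate is the median of its pass means, weighting
every visit equally regardless of dwell time.

Pass membership is defined per cell — a vehicle weaving along a cell
boundary yields interleaved per-cell passes, each isolated within its own
cell's point set.  The gap threshold defaults to 60 s: longer than plausible
within-visit dwell at urban driving speed, shorter than distinct loop
visits.  Cells visited only once are retained (their ``n_passes`` column
flags them for any downstream filtering).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grid import Grid

logger = logging.getLogger(__name__)

DEFAULT_GAP_THRESHOLD_S = 60.0


def assign_to_grid(points: pd.DataFrame, grid: Grid) -> tuple[pd.DataFrame, int]:
    """Tag each measurement point with its grid cell id.

    Points outside every active cell are dropped; the count of dropped
    points is returned alongside the tagged frame (and logged).
    """
    ids = grid.locate(points["x"].to_numpy(), points["y"].to_numpy())
    keep = ids >= 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("assign_to_grid: dropped %d out-of-domain points", n_dropped)
    out = points.loc[keep].copy()
    out["cell_id"] = ids[keep]
    return out, n_dropped


def _pass_labels(t_seconds: np.ndarray, gap_threshold_s: float) -> np.ndarray:
    """0-based pass label per point: a new pass starts after any gap > threshold."""
    if len(t_seconds) == 0:
        return np.array([], dtype=int)
    gaps = np.diff(t_seconds)
    return np.concatenate([[0], np.cumsum(gaps > gap_threshold_s)])


def isolate_drive_passes(
    cell_points: pd.DataFrame,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
    pollutants: tuple = ("ufp", "no2"),
) -> pd.DataFrame:
    """Partition one cell's points into drive passes and compute pass means.

    Input must hold a single cell's points; they are sorted by time here.
    Returns one row per pass with ``pass_id``, ``n_points`` and a
    ``mean_<pollutant>`` column per pollutant.  Empty input gives an empty
    frame.
    """
    if len(cell_points) == 0:
        cols = ["pass_id", "n_points"] + [f"mean_{p}" for p in pollutants]
        return pd.DataFrame(columns=cols)
    pts = cell_points.sort_values("t", kind="stable")
    t = pts["t"]
    t_s = t.astype("int64").to_numpy() / 1e9 if np.issubdtype(t.dtype, np.datetime64) else t.to_numpy(dtype=float)
    labels = _pass_labels(t_s, gap_threshold_s)
    g = pts.groupby(labels)
    out = pd.DataFrame({"pass_id": np.arange(labels.max() + 1), "n_points": g.size().to_numpy()})
    for p in pollutants:
        out[f"mean_{p}"] = g[p].mean().to_numpy()
    return out


def reduce_cell(passes: pd.DataFrame, pollutants: tuple = ("ufp", "no2")) -> dict:
    """Median of pass means for one cell (even counts average the central two)."""
    if len(passes) == 0:
        raise ValueError("reduce_cell requires at least one pass")
    est = {"n_passes": int(len(passes))}
    for p in pollutants:
        est[f"mm_{p}"] = float(passes[f"mean_{p}"].median())
    return est


def grid_concentration_field(
    points: pd.DataFrame,
    grid: Grid,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
    pollutants: tuple = ("ufp", "no2"),
) -> pd.DataFrame:
    """Full reduction: points -> per-cell median-of-pass-means table.

    Returns a DataFrame indexed by ``cell_id`` with ``n_passes`` and
    ``mm_<pollutant>`` columns; cells without any points are absent.
    """
    tagged, _ = assign_to_grid(points, grid)
    records = []
    for cell_id, cell_pts in tagged.groupby("cell_id"):
        passes = isolate_drive_passes(cell_pts, gap_threshold_s, pollutants)
        rec = {"cell_id": int(cell_id), **reduce_cell(passes, pollutants)}
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=["n_passes"] + [f"mm_{p}" for p in pollutants]).rename_axis("cell_id")
    return pd.DataFrame.from_records(records).set_index("cell_id").sort_index()
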