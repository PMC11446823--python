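"""Bring block-group attributes onto the monitoring grid and compute the
localized difference LD = MM - LUR.

Two distinct areal operations are used, mirroring how intensive and
extensive quantities behave:

* concentrations (intensive) are resampled by area-weighted averaging of
  overlapping block groups;
* population counts (extensive) are allocated proportionally to overlap
  area, which conserves people, and per-cell racial/ethnic shares are then
  recomputed from the allocated group counts.

Intersections are computed in projected meters; slivers below 1 m^2 are
discarded for numerical robustness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

import statsmodels.api as sm

from .grid import Grid
from .scene import SHARE_NAMES

SLIVER_M2 = 1.0


class GeometryError(ValueError):
    pass


def _cell_polygons(grid: Grid, cell_ids: np.ndarray):
    x, y = grid.cell_origin(cell_ids)
    s = grid.cell_size
    return shapely.box(x, y, x + s, y + s)


def _overlap_table(block_groups: pd.DataFrame, grid: Grid, cell_ids=None) -> pd.DataFrame:
    """Long table (cell_id, bg_index, area_m2) of cell/block-group overlaps."""
    for i, geom in enumerate(block_groups.geometry):
        if geom is None or not geom.is_valid:
            raise GeometryError(f"invalid geometry for block group index {i}")
    if cell_ids is None:
        cell_ids = grid.cell_ids()
    cells = _cell_polygons(grid, cell_ids)
    tree = STRtree(list(block_groups.geometry))
    ci, bi = tree.query(cells, predicate="intersects")
    if len(ci) == 0:
        return pd.DataFrame(columns=["cell_id", "bg_index", "area_m2"])
    inter = shapely.intersection(cells[ci], np.asarray(tree.geometries, dtype=object)[bi])
    area = shapely.area(inter)
    keep = area > SLIVER_M2
    return pd.DataFrame(
        {"cell_id": cell_ids[ci[keep]], "bg_index": bi[keep], "area_m2": area[keep]}
    )


def areal_resample(
    block_groups: pd.DataFrame, value_field, grid: Grid, cell_ids=None
) -> pd.DataFrame:
    """Area-weighted average of block-group values onto grid cells.

    value(cell) = sum_g A(g ∩ cell) v_g / sum_g A(g ∩ cell).  Cells with no
    overlap are absent from the result.  ``value_field`` may be one name or
    a list of names.
    """
    fields = [value_field] if isinstance(value_field, str) else list(value_field)
    ov = _overlap_table(block_groups, grid, cell_ids)
    if len(ov) == 0:
        return pd.DataFrame(columns=fields).rename_axis("cell_id")
    vals = block_groups[fields].to_numpy()[ov["bg_index"].to_numpy()]
    w = ov["area_m2"].to_numpy()[:, None]
    num = pd.DataFrame(vals * w, index=ov["cell_id"]).groupby(level=0).sum()
    den = pd.Series(w[:, 0], index=ov["cell_id"]).groupby(level=0).sum()
    out = num.div(den, axis=0)
    out.columns = fields
    return out.rename_axis("cell_id")


def allocate_population(
    block_groups: pd.DataFrame, grid: Grid, cell_ids=None,
    share_names: tuple = SHARE_NAMES,
) -> pd.DataFrame:
    """Allocate block-group population counts to cells by overlap fraction.

    Per racial/ethnic group r: count_r(cell) = sum_g pop_g share_{g,r}
    A(g ∩ cell)/A(g).  Returns per-cell ``pop``, per-group count columns
    (``count_*``) and recomputed share columns; conserves per-group totals
    exactly when the grid covers every block group.  Zero-area donors are
    skipped with a warning.
    """
    import warnings

    bgs = block_groups.reset_index(drop=True)
    areas = np.array([g.area for g in bgs.geometry])
    if (areas <= 0).any():
        warnings.warn("skipping zero-area block groups")
    ov = _overlap_table(bgs, grid, cell_ids)
    ov = ov[areas[ov["bg_index"]] > 0]
    if len(ov) == 0:
        cols = ["pop"] + [f"count_{s}" for s in share_names] + list(share_names)
        return pd.DataFrame(columns=cols).rename_axis("cell_id")
    bi = ov["bg_index"].to_numpy()
    frac = ov["area_m2"].to_numpy() / areas[bi]
    pop_g = bgs["pop"].to_numpy()[bi]
    counts = {}
    for s in share_names:
        counts[f"count_{s}"] = pop_g * bgs[s].to_numpy()[bi] * frac
    alloc = pd.DataFrame(counts, index=ov["cell_id"]).groupby(level=0).sum()
    alloc["pop"] = alloc.sum(axis=1)
    for s in share_names:
        with np.errstate(invalid="ignore", divide="ignore"):
            alloc[s] = np.where(alloc["pop"] > 0, alloc[f"count_{s}"] / alloc["pop"], 0.0)
    cols = ["pop"] + [f"count_{s}" for s in share_names] + list(share_names)
    return alloc[cols].rename_axis("cell_id")


def compute_ld(mm: pd.DataFrame, lur: pd.DataFrame, pollutants=("ufp", "no2")) -> pd.DataFrame:
    """Localized difference per cell: ld = mm - lur, on cells where both exist.

    Positive LD marks cells where mobile-monitoring observations exceed the
    national-model prediction (local underprediction).  The number of cells
    excluded for a missing side is stored in ``result.attrs['n_excluded']``.
    """
    joined = mm.join(lur, how="inner")
    out = pd.DataFrame(index=joined.index)
    for p in pollutants:
        out[f"mm_{p}"] = joined[f"mm_{p}"]
        out[f"lur_{p}"] = joined[f"lur_{p}"]
        out[f"ld_{p}"] = joined[f"mm_{p}"] - joined[f"lur_{p}"]
    out = out.dropna()
    out.attrs["n_excluded"] = int(len(mm.index.union(lur.index)) - len(out))
    return out


def ols_compare(mm: pd.Series, lur: pd.Series) -> dict:
    """OLS of MM on LUR plus marginal distribution summaries.

    Returns slope, intercept, r2, p_value (slope t-test) and the median and
    quartiles of both inputs.  A zero-variance predictor is flagged instead
    of fitted.
    """
    df = pd.concat({"mm": mm, "lur": lur}, axis=1).dropna()
    if len(df) < 3:
        raise ValueError("ols_compare needs at least 3 paired cells")
    out = {
        "n": int(len(df)),
        "mm_median": float(df["mm"].median()),
        "mm_q25": float(df["mm"].quantile(0.25)),
        "mm_q75": float(df["mm"].quantile(0.75)),
        "lur_median": float(df["lur"].median()),
        "lur_q25": float(df["lur"].quantile(0.25)),
        "lur_q75": float(df["lur"].quantile(0.75)),
    }
    if np.isclose(df["lur"].var(ddof=0), 0.0):
        out.update(slope=np.nan, intercept=np.nan, r2=np.nan, p_value=np.nan,
                   degenerate=True)
        return out
    res = sm.OLS(df["mm"].to_numpy(), sm.add_constant(df["lur"].to_numpy())).fit()
    out.update(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        degenerate=False,
    )
    return out
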