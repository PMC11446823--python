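"""Synthetic urban scenes with known pollution ground truth.

A scene emulates the inputs of a hyperlocal air-quality campaign: a planar
domain of monitored neighborhoods tiled by 100 m grid cells, road polylines
by class (residential, arterial, highway, on-ramp), sparse point sources
(food service, gas stations), industrial polygons, census-style block groups
carrying population and five racial/ethnic shares, smooth block-group-level
"national model" predictions, and 1 Hz drive traces sampled on the road
network.  Ground-truth long-term concentration surfaces are built from an
exponential near-source decay kernel, so every downstream stage (gridding,
harmonization, feature extraction, tree-ensemble inference) can be tested
against known parameters.

Two pollutants are carried throughout: ultrafine particle count (``ufp``,
in thousands of particles per cm^3) and NO2 mixing ratio (``no2``, ppb).

All randomness flows from a single integer seed; identical config + seed
yields identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union
import shapely

from .grid import Grid

POLLUTANTS = ("ufp", "no2")
ROAD_CLASSES = ("residential", "arterial", "highway", "on_ramp")
POINT_CLASSES = ("food_service", "gas_stations")
SOURCE_TYPES = ROAD_CLASSES + POINT_CLASSES + ("industrial",)
SHARE_NAMES = ("share_asian", "share_black", "share_other", "share_white", "share_hispanic")


class SceneConfigError(ValueError):
    """Raised for inconsistent scene configuration."""


def _default_road_spacing():
    return {"residential": 200.0, "arterial": 500.0}


def _default_background():
    # long-term urban background: UFP in 10^3 particles/cm^3, NO2 in ppb
    return {"ufp": 6.0, "no2": 4.0}


def _default_strengths():
    # excess concentration contributed at zero distance from one source
    return {
        "ufp": {
            "residential": 0.4,
            "arterial": 2.5,
            "highway": 25.0,
            "on_ramp": 8.0,
            "food_service": 5.0,
            "gas_stations": 3.0,
            "industrial": 6.0,
        },
        "no2": {
            "residential": 0.15,
            "arterial": 1.0,
            "highway": 5.0,
            "on_ramp": 2.0,
            "food_service": 0.4,
            "gas_stations": 0.8,
            "industrial": 1.5,
        },
    }


def _default_decay():
    # meters; all lengths give a 2-10x excess decay between 50 m and 300 m
    return {
        "residential": 160.0,
        "arterial": 180.0,
        "highway": 250.0,
        "on_ramp": 200.0,
        "food_service": 160.0,
        "gas_stations": 160.0,
        "industrial": 220.0,
    }


def _default_noise():
    # sd of log pass-level multiplicative noise (temporal variability)
    return {"ufp": 0.4, "no2": 0.25}


def _default_lur_bias():
    # additive bias of national predictions: negative bias -> positive mean
    # localized difference (national model underpredicts), emulating the
    # observed underestimation of UFP and near-neutral NO2
    return {"ufp": -12.4, "no2": 0.9}


def _default_base_shares():
    # domain-wide mean composition: asian, black, other, white, hispanic
    return (0.25, 0.10, 0.05, 0.35, 0.25)


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    ``demo_source_corr`` controls residential sorting around sources: the
    white-non-Hispanic Dirichlet concentration of each block group is tilted
    by local traffic-source density, with the sign of the induced
    correlation between white share and source density equal to the sign of
    this parameter.  Negative values (the default) place communities of
    color disproportionately near sources.
    """

    seed: int = 0
    n_neighborhoods: int = 4
    neighborhood_size_m: int = 1000
    cell_size_m: int = 100
    block_group_size_m: int = 500
    road_grid_spacing_m: dict = field(default_factory=_default_road_spacing)
    include_highway: bool = True
    n_onramps: int = 3
    n_food_service: int = 12
    n_gas: int = 6
    n_industrial_polys: int = 3
    background: dict = field(default_factory=_default_background)
    source_strengths: dict = field(default_factory=_default_strengths)
    decay_length_m: dict = field(default_factory=_default_decay)
    noise_sd: dict = field(default_factory=_default_noise)
    n_drive_passes_per_cell: int = 5
    drive_speed_ms: float = 9.0
    lur_bias: dict = field(default_factory=_default_lur_bias)
    demo_source_corr: float = -0.5
    demo_tilt_scale: float = 2.5
    mean_bg_pop: float = 1200.0
    dirichlet_conc: float = 12.0
    base_shares: tuple = field(default_factory=_default_base_shares)

    def __post_init__(self):
        if self.cell_size_m <= 0 or self.neighborhood_size_m <= 0:
            raise SceneConfigError("cell and neighborhood sizes must be positive")
        if self.neighborhood_size_m % self.cell_size_m != 0:
            raise SceneConfigError("neighborhood size must be a multiple of cell size")
        if self.block_group_size_m % self.cell_size_m != 0:
            raise SceneConfigError("block group size must be a multiple of cell size")
        if self.neighborhood_size_m % self.block_group_size_m != 0:
            raise SceneConfigError("neighborhood size must be a multiple of block group size")
        if self.n_neighborhoods < 1:
            raise SceneConfigError("need at least one neighborhood")
        if self.n_drive_passes_per_cell < 1:
            raise SceneConfigError("n_drive_passes_per_cell must be >= 1")
        if not -1.0 <= self.demo_source_corr <= 1.0:
            raise SceneConfigError("demo_source_corr must lie in [-1, 1]")
        for v in self.road_grid_spacing_m.values():
            if v <= 0:
                raise SceneConfigError("road spacing must be positive")
        for p in POLLUTANTS:
            if self.background[p] <= 0:
                raise SceneConfigError("background concentrations must be positive")
        if abs(sum(self.base_shares) - 1.0) > 1e-9:
            raise SceneConfigError("base_shares must sum to 1")


@dataclass
class Scene:
    """A generated scene: geometry, block groups and truth surfaces.

    ``block_groups`` is a DataFrame with a shapely ``geometry`` column plus
    (after demographics / national-prediction generation) ``pop``, the five
    ``share_*`` columns and ``lur_ufp`` / ``lur_no2``.  ``truth`` is a
    DataFrame indexed by cell id with columns ``truth_ufp`` / ``truth_no2``.
    """

    config: SceneConfig
    grid: Grid
    roads: dict  # class -> list[LineString]
    food_service: list
    gas_stations: list
    industrial: list
    block_groups: pd.DataFrame
    domain: object = None  # shapely polygon union of neighborhoods
    truth: pd.DataFrame = None

    def layers(self) -> dict:
        """Geometry layers keyed by the seven source-type names."""
        out = {cls: self.roads[cls] for cls in ROAD_CLASSES}
        out["food_service"] = self.food_service
        out["gas_stations"] = self.gas_stations
        out["industrial"] = self.industrial
        return out


# ---------------------------------------------------------------------------
# geometry construction


def _neighborhood_boxes(config: SceneConfig):
    n, size = config.n_neighborhoods, config.neighborhood_size_m
    ncols = math.ceil(math.sqrt(n))
    boxes = []
    for i in range(n):
        cx, cy = i % ncols, i // ncols
        boxes.append(box(cx * size, cy * size, (cx + 1) * size, (cy + 1) * size))
    return boxes


def _grid_lines(x_lo, x_hi, y_lo, y_hi, spacing, offset, domain):
    """Horizontal + vertical lines at offset + k*spacing, clipped to domain."""
    lines = []
    x = x_lo + offset
    while x < x_hi:
        lines.append(LineString([(x, y_lo), (x, y_hi)]))
        x += spacing
    y = y_lo + offset
    while y < y_hi:
        lines.append(LineString([(x_lo, y), (x_hi, y)]))
        y += spacing
    out = []
    for ln in lines:
        clipped = ln.intersection(domain)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "LineString":
            out.append(clipped)
        else:  # MultiLineString across discontinuous neighborhoods
            out.extend(g for g in clipped.geoms if g.geom_type == "LineString")
    return out


def generate_scene(config: SceneConfig) -> Scene:
    """Build scene geometry, block groups, truth, demographics and national
    predictions, deterministically from ``config.seed``.

    Drive traces are generated separately by :func:`simulate_drive_traces`.
    """
    rng = np.random.default_rng(config.seed)
    nb_boxes = _neighborhood_boxes(config)
    domain = unary_union(nb_boxes)
    x_lo, y_lo, x_hi, y_hi = domain.bounds

    s = float(config.cell_size_m)
    ncols = int(round((x_hi - x_lo) / s))
    nrows = int(round((y_hi - y_lo) / s))
    active = np.zeros((nrows, ncols), dtype=bool)
    size_c = config.neighborhood_size_m // config.cell_size_m
    n_nb_cols = math.ceil(math.sqrt(config.n_neighborhoods))
    for i in range(config.n_neighborhoods):
        cx, cy = i % n_nb_cols, i // n_nb_cols
        active[cy * size_c:(cy + 1) * size_c, cx * size_c:(cx + 1) * size_c] = True
    grid = Grid(x_lo, y_lo, ncols, nrows, s, active)

    roads = {cls: [] for cls in ROAD_CLASSES}
    sp = config.road_grid_spacing_m

    def _offset(spacing):
        # keep road lines off cell edges so each line runs mid-cell
        off = spacing / 2.0
        if off % config.cell_size_m == 0:
            off += config.cell_size_m / 2.0
        return off

    if sp.get("residential"):
        roads["residential"] = _grid_lines(
            x_lo, x_hi, y_lo, y_hi, sp["residential"], _offset(sp["residential"]), domain
        )
    if sp.get("arterial"):
        roads["arterial"] = _grid_lines(
            x_lo, x_hi, y_lo, y_hi, sp["arterial"], _offset(sp["arterial"]), domain
        )

    highway_y = None
    if config.include_highway:
        # one east-west highway at a random height, kept off the other road
        # lines by snapping to a 10 m lattice offset by 3 m
        highway_y = y_lo + 3.0 + 10.0 * rng.integers(1, max(2, int((y_hi - y_lo) / 10) - 1))
        hw = LineString([(x_lo, highway_y), (x_hi, highway_y)]).intersection(domain)
        if not hw.is_empty:
            if hw.geom_type == "LineString":
                roads["highway"] = [hw]
            else:
                roads["highway"] = [g for g in hw.geoms if g.geom_type == "LineString"]
        for _ in range(config.n_onramps):
            x = rng.uniform(x_lo + 100, x_hi - 100)
            side = 1.0 if rng.random() < 0.5 else -1.0
            ramp = LineString(
                [(x, highway_y), (x + 110.0, highway_y + side * 110.0)]
            ).intersection(domain)
            if not ramp.is_empty and ramp.geom_type == "LineString" and ramp.length > 1:
                roads["on_ramp"].append(ramp)

    def _near_road_points(n, jitter=60.0):
        pts = []
        candidates = roads["arterial"] or roads["residential"]
        for _ in range(n):
            if candidates:
                ln = candidates[rng.integers(len(candidates))]
                base = ln.interpolate(rng.uniform(0, ln.length))
                p = Point(base.x + rng.normal(0, jitter), base.y + rng.normal(0, jitter))
            else:
                p = Point(rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi))
            if not domain.contains(p):
                p = shapely.ops.nearest_points(domain, p)[0]
            pts.append(p)
        return pts

    food = _near_road_points(config.n_food_service)
    gas = _near_road_points(config.n_gas)

    industrial = []
    for _ in range(config.n_industrial_polys):
        w, h = rng.uniform(150, 400), rng.uniform(150, 400)
        cx = rng.uniform(x_lo + 100, x_hi - 100)
        if highway_y is not None:
            cy = highway_y + rng.uniform(-300, 300)
        else:
            cy = rng.uniform(y_lo + 100, y_hi - 100)
        poly = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2).intersection(domain)
        if not poly.is_empty and poly.area > 0:
            industrial.append(poly)

    block_groups = _make_block_groups(config, domain)
    scene = Scene(
        config=config,
        grid=grid,
        roads=roads,
        food_service=food,
        gas_stations=gas,
        industrial=industrial,
        block_groups=block_groups,
        domain=domain,
    )
    scene.truth = truth_surface(scene, config)
    generate_demographics(scene, config, rng=rng)
    generate_national_predictions(scene, config, rng=rng)
    return scene


def _make_block_groups(config: SceneConfig, domain) -> pd.DataFrame:
    size = config.block_group_size_m
    per_side = config.neighborhood_size_m // size
    rows = []
    bg_id = 0
    for i, nb in enumerate(_neighborhood_boxes(config)):
        nx_lo, ny_lo, _, _ = nb.bounds
        for r in range(per_side):
            for c in range(per_side):
                geom = box(
                    nx_lo + c * size, ny_lo + r * size,
                    nx_lo + (c + 1) * size, ny_lo + (r + 1) * size,
                )
                rows.append({"bg_id": bg_id, "neighborhood": i, "geometry": geom})
                bg_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth surfaces


def truth_surface(scene: Scene, config: SceneConfig) -> pd.DataFrame:
    """Ground-truth long-term concentration per cell and pollutant.

    truth(cell) = background + sum over individual sources of
    strength * exp(-d(cell center, source) / decay_length), where each road
    polyline, each point, and each industrial polygon is one source.
    Contributions are additive, so coincident sources stack linearly.
    """
    ids = scene.grid.cell_ids()
    centers = scene.grid.cell_center(ids)
    pts = shapely.points(centers[:, 0], centers[:, 1])
    excess = {p: np.zeros(len(ids)) for p in POLLUTANTS}
    for stype, geoms in scene.layers().items():
        L = config.decay_length_m[stype]
        for g in geoms:
            d = shapely.distance(pts, g)
            kern = np.exp(-d / L)
            for p in POLLUTANTS:
                excess[p] += config.source_strengths[p][stype] * kern
    out = pd.DataFrame(index=pd.Index(ids, name="cell_id"))
    for p in POLLUTANTS:
        out[f"truth_{p}"] = config.background[p] + excess[p]
    return out


# ---------------------------------------------------------------------------
# drive traces


def simulate_drive_traces(scene: Scene, config: SceneConfig) -> pd.DataFrame:
    """Simulate 1 Hz weekday-daytime drive traces covering every road.

    The fleet traverses the full network ``n_drive_passes_per_cell`` times;
    each (traversal, road) leg gets its own start slot separated by more
    than any plausible pass gap, so every cell touched by a road receives at
    least that many temporally separated passes (cells at intersections of
    k roads receive k per traversal).  Measurement noise is a lognormal
    factor with median 1 drawn once per leg: pass means are then unbiased in
    the median for cell truth, while their arithmetic mean is inflated by
    exp(sd^2 / 2) (the lognormal mean correction).

    Returns a DataFrame with columns t (datetime64), x, y, ufp, no2.
    """
    if scene.truth is None:
        scene.truth = truth_surface(scene, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A11CE]))
    v = config.drive_speed_ms
    legs = []
    for cls in ROAD_CLASSES:
        legs.extend(scene.roads[cls])
    if not legs:
        return pd.DataFrame(columns=["t", "x", "y", "ufp", "no2"])

    max_dur = max(int(math.ceil(ln.length / v)) for ln in legs) + 1
    slot = max_dur + 120  # seconds between leg starts; > any gap threshold
    day_start_s = 8 * 3600
    day_len_s = 10 * 3600  # weekday 08:00-18:00
    legs_per_day = max(1, day_len_s // slot)

    base = pd.Timestamp("2016-06-06 00:00:00")  # a Monday
    truth = scene.truth
    frames = []
    leg_counter = 0
    for k in range(config.n_drive_passes_per_cell):
        for ln in legs:
            day, in_day = divmod(leg_counter, legs_per_day)
            week, wday = divmod(day, 5)  # weekdays only
            t0 = base + pd.Timedelta(days=7 * week + wday, seconds=day_start_s + in_day * slot)
            n_pts = int(math.floor(ln.length / v)) + 1
            dist = np.arange(n_pts) * v
            pos = ln.interpolate(dist)
            x = np.array([p.x for p in pos])
            y = np.array([p.y for p in pos])
            ids = scene.grid.locate(x, y)
            keep = ids >= 0
            factor = {p: math.exp(rng.normal(0.0, config.noise_sd[p])) for p in POLLUTANTS}
            df = pd.DataFrame(
                {
                    "t": t0 + pd.to_timedelta(np.arange(n_pts)[keep], unit="s"),
                    "x": x[keep],
                    "y": y[keep],
                }
            )
            for p in POLLUTANTS:
                df[p] = truth[f"truth_{p}"].loc[ids[keep]].to_numpy() * factor[p]
            frames.append(df)
            leg_counter += 1
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# block-group attributes


def _bg_road_density(scene: Scene, classes=("highway", "arterial")) -> np.ndarray:
    """Road length per unit area within each block group, for given classes."""
    dens = np.zeros(len(scene.block_groups))
    geoms = [g for cls in classes for g in scene.roads[cls]]
    if not geoms:
        return dens
    net = unary_union(geoms)
    for i, bg in enumerate(scene.block_groups.geometry):
        dens[i] = net.intersection(bg).length / bg.area
    return dens


def generate_demographics(scene: Scene, config: SceneConfig, rng=None) -> pd.DataFrame:
    """Draw block-group population and five racial/ethnic shares.

    Shares come from a Dirichlet whose white-non-Hispanic concentration is
    tilted by standardized local traffic-source density; the tilt strength
    and sign follow ``config.demo_source_corr`` (see :class:`SceneConfig`).
    Writes ``pop`` and the five share columns onto ``scene.block_groups``
    and returns that frame.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDE30]))
    bgs = scene.block_groups
    dens = _bg_road_density(scene)
    sd = dens.std()
    z = (dens - dens.mean()) / sd if sd > 0 else np.zeros_like(dens)

    base = np.asarray(config.base_shares, dtype=float)
    conc = config.dirichlet_conc
    tilt = config.demo_source_corr * config.demo_tilt_scale
    shares = np.empty((len(bgs), 5))
    for i in range(len(bgs)):
        alpha = conc * base.copy()
        alpha[3] = alpha[3] * math.exp(tilt * z[i])  # white share tilt
        shares[i] = rng.dirichlet(alpha)
    pop = rng.poisson(config.mean_bg_pop * np.exp(rng.normal(0.0, 0.4, len(bgs))))
    bgs["pop"] = pop.astype(float)
    for j, name in enumerate(SHARE_NAMES):
        bgs[name] = shares[:, j]
    return bgs


def generate_national_predictions(scene: Scene, config: SceneConfig, rng=None) -> pd.DataFrame:
    """Smooth block-group-level predictions emulating a national model.

    For each pollutant the block-group mean of the truth surface is
    regressed (OLS) on coarse covariates — total road length in the block
    group and population — and the fitted values, plus a configurable
    additive bias, become the predictions.  Being fitted values of a linear
    smoother they are smoother than truth and by construction miss
    within-block-group extremes.  Writes ``lur_ufp`` / ``lur_no2`` onto
    ``scene.block_groups``.
    """
    if scene.truth is None:
        scene.truth = truth_surface(scene, config)
    bgs = scene.block_groups
    if "pop" not in bgs.columns:
        generate_demographics(scene, config, rng=rng)

    ids = scene.grid.cell_ids()
    centers = scene.grid.cell_center(ids)
    pts = shapely.points(centers[:, 0], centers[:, 1])
    # cells are strictly interior to exactly one block group by construction
    bg_mean = {p: np.zeros(len(bgs)) for p in POLLUTANTS}
    road_len = np.zeros(len(bgs))
    all_roads = [g for cls in ROAD_CLASSES for g in scene.roads[cls]]
    net = unary_union(all_roads) if all_roads else None
    for i, bg in enumerate(bgs.geometry):
        inside = shapely.contains(bg, pts)
        for p in POLLUTANTS:
            vals = scene.truth[f"truth_{p}"].to_numpy()[inside]
            bg_mean[p][i] = vals.mean() if len(vals) else config.background[p]
        if net is not None:
            road_len[i] = net.intersection(bg).length

    X = np.column_stack([np.ones(len(bgs)), road_len, bgs["pop"].to_numpy()])
    for p in POLLUTANTS:
        y = bg_mean[p]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta + config.lur_bias[p]
        bgs[f"lur_{p}"] = np.maximum(pred, 0.0)
    return bgs
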