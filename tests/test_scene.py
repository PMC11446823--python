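"""Synthetic scene generator: geometry, truth kernel, traces, demographics."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from localdiff.scene import (
    SHARE_NAMES,
    Scene,
    SceneConfig,
    SceneConfigError,
    generate_scene,
    simulate_drive_traces,
    truth_surface,
)


def test_single_neighborhood_tiles_into_100_cells(small_scene):
    scene, _ = small_scene
    assert scene.grid.n_cells == 100
    assert len(scene.block_groups) == 4


def test_same_seed_reproduces_scene_exactly():
    a = generate_scene(SceneConfig(seed=3, n_neighborhoods=2))
    b = generate_scene(SceneConfig(seed=3, n_neighborhoods=2))
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(
        a.block_groups.drop(columns="geometry"), b.block_groups.drop(columns="geometry")
    )
    assert all(ga.equals(gb) for ga, gb in zip(a.block_groups.geometry, b.block_groups.geometry))
    for cls in a.roads:
        assert [g.wkt for g in a.roads[cls]] == [g.wkt for g in b.roads[cls]]


def test_invalid_config_rejected():
    with pytest.raises(SceneConfigError):
        SceneConfig(neighborhood_size_m=950)  # not a multiple of cell size
    with pytest.raises(SceneConfigError):
        SceneConfig(n_drive_passes_per_cell=0)
    with pytest.raises(SceneConfigError):
        SceneConfig(demo_source_corr=1.5)


def test_absent_point_source_gives_empty_layer():
    scene = generate_scene(SceneConfig(seed=1, n_neighborhoods=1, n_food_service=0))
    assert scene.food_service == []


def test_block_group_shares_sum_to_one(small_scene):
    scene, _ = small_scene
    sums = scene.block_groups[list(SHARE_NAMES)].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def _point_source_scene(strength, decay, n_points=1):
    """Minimal scene: no roads, one (or more) food-service point at origin cell."""
    cfg = SceneConfig(
        seed=0, n_neighborhoods=1,
        road_grid_spacing_m={}, include_highway=False, n_onramps=0,
        n_food_service=0, n_gas=0, n_industrial_polys=0,
    )
    scene = generate_scene(cfg)
    cfg.source_strengths["ufp"]["food_service"] = strength
    cfg.decay_length_m["food_service"] = decay
    scene.food_service = [Point(50.0, 50.0)] * n_points
    return scene, cfg


def test_truth_is_background_without_sources():
    cfg = SceneConfig(
        seed=0, n_neighborhoods=1,
        road_grid_spacing_m={}, include_highway=False, n_onramps=0,
        n_food_service=0, n_gas=0, n_industrial_polys=0,
    )
    scene = generate_scene(cfg)
    assert np.allclose(scene.truth["truth_ufp"], cfg.background["ufp"])
    assert np.allclose(scene.truth["truth_no2"], cfg.background["no2"])


def test_exponential_kernel_excess_ratio_is_closed_form():
    # excess(50 m) / excess(300 m) = exp(250 / L); L = 250 gives e
    scene, cfg = _point_source_scene(strength=10.0, decay=250.0)
    src = scene.food_service[0]
    truth = truth_surface(scene, cfg)
    centers = scene.grid.cell_center(scene.grid.cell_ids())
    d = np.hypot(centers[:, 0] - src.x, centers[:, 1] - src.y)
    excess = truth["truth_ufp"].to_numpy() - cfg.background["ufp"]
    # interpolate the kernel at exactly 50 and 300 m via the closed form
    assert np.allclose(excess, 10.0 * np.exp(-d / 250.0), atol=1e-12)
    ratio = math.exp(-50.0 / 250.0) / math.exp(-300.0 / 250.0)
    assert ratio == pytest.approx(math.e, rel=1e-12)


def test_two_coincident_sources_double_the_excess():
    one, cfg1 = _point_source_scene(10.0, 250.0, n_points=1)
    two, cfg2 = _point_source_scene(10.0, 250.0, n_points=2)
    ex1 = truth_surface(one, cfg1)["truth_ufp"] - cfg1.background["ufp"]
    ex2 = truth_surface(two, cfg2)["truth_ufp"] - cfg2.background["ufp"]
    assert np.allclose(ex2, 2.0 * ex1, rtol=1e-12)


def test_default_decay_lengths_give_2_to_10_fold_decay():
    cfg = SceneConfig()
    for stype, L in cfg.decay_length_m.items():
        ratio = math.exp(250.0 / L)
        assert 2.0 <= ratio <= 10.0, stype


def test_noise_free_traces_equal_cell_truth(small_scene):
    scene, _ = small_scene
    cfg = SceneConfig(seed=7, n_neighborhoods=1, noise_sd={"ufp": 0.0, "no2": 0.0},
                      n_drive_passes_per_cell=1)
    tr = simulate_drive_traces(scene, cfg)
    ids = scene.grid.locate(tr["x"].to_numpy(), tr["y"].to_numpy())
    truth = scene.truth["truth_ufp"].loc[ids].to_numpy()
    assert np.allclose(tr["ufp"].to_numpy(), truth, rtol=1e-12)


def test_traces_are_weekday_daytime(small_scene):
    scene, cfg = small_scene
    tr = simulate_drive_traces(scene, cfg)
    t = pd.DatetimeIndex(tr["t"])
    assert (t.dayofweek < 5).all()
    assert (t.hour >= 8).all() and (t.hour < 18).all()


def test_demographic_tilt_sign_and_null():
    # strong negative tilt -> white share negatively correlated with
    # traffic-source density; zero tilt -> near-zero correlation
    from localdiff.scene import _bg_road_density

    def corr_for(tilt, seed, n_nb=25):
        cfg = SceneConfig(seed=seed, n_neighborhoods=n_nb, demo_source_corr=tilt)
        scene = generate_scene(cfg)
        dens = _bg_road_density(scene)
        return np.corrcoef(scene.block_groups["share_white"], dens)[0, 1]

    assert corr_for(-0.8, seed=11) < -0.3
    # 25 neighborhoods x 4 block groups x 5 seeds = 500 draws of the null
    rs = [corr_for(0.0, seed=s) for s in (1, 2, 3, 4, 5)]
    assert abs(np.mean(rs)) < 0.1


def test_national_predictions_are_smoother_than_truth(medium_scene):
    scene, cfg, _, _ = medium_scene
    # block-group-mean truth variance bounds the fitted-value variance
    import shapely

    ids = scene.grid.cell_ids()
    centers = scene.grid.cell_center(ids)
    pts = shapely.points(centers[:, 0], centers[:, 1])
    for p in ("ufp", "no2"):
        means = []
        for bg in scene.block_groups.geometry:
            inside = shapely.contains(bg, pts)
            means.append(scene.truth[f"truth_{p}"].to_numpy()[inside].mean())
        assert scene.block_groups[f"lur_{p}"].var() <= np.var(means, ddof=1) + 1e-9


def test_constant_truth_yields_zero_ld_predictions():
    cfg = SceneConfig(
        seed=2, n_neighborhoods=1,
        road_grid_spacing_m={"residential": 200.0}, include_highway=False,
        n_onramps=0, n_food_service=0, n_gas=0, n_industrial_polys=0,
        lur_bias={"ufp": 0.0, "no2": 0.0},
    )
    cfg.source_strengths = {p: {k: 0.0 for k in cfg.source_strengths[p]} for p in cfg.source_strengths}
    scene = generate_scene(cfg)
    assert np.allclose(scene.truth["truth_ufp"], cfg.background["ufp"])
    assert np.allclose(scene.block_groups["lur_ufp"], cfg.background["ufp"], rtol=1e-9)


def test_configured_bias_shifts_mean_ld():
    # generator bookkeeping: domain-mean prediction shifts by the bias, so
    # mean (block-group-mean truth - prediction) equals -bias
    import shapely

    cfg = SceneConfig(seed=5, n_neighborhoods=4, lur_bias={"ufp": -12.0, "no2": 0.0})
    scene = generate_scene(cfg)
    ids = scene.grid.cell_ids()
    centers = scene.grid.cell_center(ids)
    pts = shapely.points(centers[:, 0], centers[:, 1])
    means = np.array([
        scene.truth["truth_ufp"].to_numpy()[shapely.contains(bg, pts)].mean()
        for bg in scene.block_groups.geometry
    ])
    ld_bg = means - scene.block_groups["lur_ufp"].to_numpy()
    assert ld_bg.mean() == pytest.approx(12.0, abs=0.05)


def test_sparse_source_layers_are_mostly_zero(medium_scene):
    _, _, kls, _ = medium_scene
    for col in ("KLS_highway_50", "KLS_on_ramp_50", "KLS_industrial_50"):
        assert (kls[col] == 0).mean() > 0.5
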