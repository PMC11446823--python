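import numpy as np
import pytest

from localdiff.bart import BART, BartConfig
from localdiff.features import build_feature_matrix
from localdiff.harmonize import allocate_population
from localdiff.scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One 1 km^2 neighborhood: 100 cells, 4 block groups."""
    cfg = SceneConfig(seed=7, n_neighborhoods=1)
    return generate_scene(cfg), cfg


@pytest.fixture(scope="session")
def medium_scene():
    """Four neighborhoods (400 cells, 16 block groups), sources confounded
    with demographics."""
    cfg = SceneConfig(seed=21, n_neighborhoods=4, demo_source_corr=-0.8)
    scene = generate_scene(cfg)
    kls = build_feature_matrix(scene.layers(), scene.grid)
    alloc = allocate_population(scene.block_groups, scene.grid).reindex(kls.index)
    return scene, cfg, kls, alloc


@pytest.fixture(scope="session")
def step_fit():
    """BART fitted to a one-feature step function with unit noise."""
    rng = np.random.default_rng(42)
    X = rng.uniform(size=(500, 5))
    y = 10.0 * (X[:, 0] > 0.5) + rng.normal(0.0, 1.0, 500)
    cfg = BartConfig(n_trees=20, n_burn=100, n_post=300, seed=5)
    res = BART(y, X, config=cfg).fit()
    return X, y, res
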