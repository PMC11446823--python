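"""Sum-of-trees sampler, partial dependence, VIP, fit diagnostics."""

import numpy as np
import pandas as pd
import pytest

from localdiff.bart import (
    BART,
    BartConfig,
    BartPosterior,
    TreeSnapshot,
    _tree_predict,
    nrmse,
    partial_dependence,
    predict,
    pseudo_r2,
    top_variables,
    variable_inclusion_proportions,
)


def _leaf(value):
    return TreeSnapshot(
        np.array([-1], dtype=np.int32), np.zeros(1), np.array([-1], dtype=np.int32),
        np.array([-1], dtype=np.int32), np.array([float(value)]),
    )


def _stump(j, cut, left_val, right_val):
    return TreeSnapshot(
        np.array([j, -1, -1], dtype=np.int32),
        np.array([cut, 0.0, 0.0]),
        np.array([1, -1, -1], dtype=np.int32),
        np.array([2, -1, -1], dtype=np.int32),
        np.array([0.0, float(left_val), float(right_val)]),
    )


def _posterior(trees_per_draw, y_min, y_max, p, n=2, feature_names=None):
    n_draws = len(trees_per_draw)
    return BartPosterior(
        trees=trees_per_draw,
        sigma2=np.ones(n_draws),
        y_min=y_min, y_max=y_max,
        feature_names=feature_names or [f"x{j}" for j in range(p)],
        in_sample_scaled=np.zeros((n_draws, n)),
        split_counts=np.zeros((n_draws, p)),
        config=BartConfig(n_trees=len(trees_per_draw[0]), n_post=n_draws),
    )


class TestHandCraftedTrees:
    def test_single_split_tree_piecewise_prediction(self):
        # scaled leaf values -0.5 / +0.5 map to 0 / 10 with y in [0, 10]
        post = _posterior([[_stump(0, 0.5, -0.5, 0.5)]], 0.0, 10.0, p=2)
        X = np.array([[0.2, 9.0], [0.49999, -1.0], [0.5, 0.0], [0.9, 2.0]])
        mean = predict(post, X)
        assert mean == pytest.approx([0.0, 0.0, 10.0, 10.0])

    def test_prediction_mean_equals_mean_of_draws(self):
        post = _posterior(
            [[_stump(0, 0.5, -0.5, 0.5)], [_leaf(0.0)]], 0.0, 10.0, p=1
        )
        X = np.array([[0.1], [0.9]])
        mean, draws = predict(post, X, return_draws=True)
        assert np.allclose(mean, draws.mean(axis=0))
        assert draws.shape == (2, 2)

    def test_sum_of_trees_adds_contributions(self):
        trees = [[_stump(0, 0.5, -0.25, 0.25), _stump(0, 0.5, -0.25, 0.25)]]
        post = _posterior(trees, 0.0, 10.0, p=1)
        assert predict(post, np.array([[0.9]]))[0] == pytest.approx(10.0)

    def test_unknown_column_raises(self):
        post = _posterior([[_leaf(0.0)]], 0.0, 1.0, p=2, feature_names=["a", "b"])
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(post, pd.DataFrame({"a": [1.0], "c": [2.0]}))

    def test_hand_crafted_pdp_is_step_at_median(self):
        # one split on x0 at 0.5: PDP = 0 below, 10 above, for any X
        post = _posterior([[_stump(0, 0.5, -0.5, 0.5)]], 0.0, 10.0, p=2)
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(40, 2))
        pdp = partial_dependence(post, X, 0, eval_values=[0.25, 0.75])
        assert pdp.mean == pytest.approx([0.0, 10.0])

    def test_pseudo_r2_and_nrmse_hand_case(self):
        # y = {1, 3}, predictions {2, 2}: R2 = 1 - 2/2 = 0, NRMSE = 1/2
        post = _posterior([[_leaf(0.0)]], 1.0, 3.0, p=1)  # predicts 2 everywhere
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 3.0])
        assert pseudo_r2(post, X, y) == pytest.approx(0.0)
        assert nrmse(post, X, y) == pytest.approx(0.5)

    def test_nrmse_zero_mean_flagged_infinite(self):
        post = _posterior([[_leaf(0.0)]], -1.0, 1.0, p=1)
        with pytest.warns(UserWarning, match="undefined"):
            assert nrmse(post, np.zeros((2, 1)), np.array([-1.0, 1.0])) == np.inf


class TestFit:
    def test_constant_response_degenerate(self):
        X = np.random.default_rng(0).uniform(size=(20, 3))
        with pytest.warns(UserWarning, match="constant"):
            res = BART(np.full(20, 7.5), X).fit()
        assert np.allclose(res.fitted_values, 7.5)
        assert res.pseudo_r2 == 0.0

    def test_step_function_recovered_at_plateaus(self, step_fit):
        X, y, res = step_fit
        pred = res.fitted_values
        lo = pred[X[:, 0] < 0.3].mean()
        hi = pred[X[:, 0] > 0.7].mean()
        assert abs(lo - 0.0) < 1.0
        assert abs(hi - 10.0) < 1.0

    def test_friedman_signal_pseudo_r2(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(500, 10))
        y = (10 * np.sin(np.pi * X[:, 0] * X[:, 1]) + 20 * (X[:, 2] - 0.5) ** 2
             + 10 * X[:, 3] + 5 * X[:, 4] + rng.normal(0, 1, 500))
        res = BART(y, X, config=BartConfig(n_trees=50, n_burn=200, n_post=300, seed=3)).fit()
        assert res.pseudo_r2 > 0.7

    def test_missing_values_rejected(self):
        X = np.ones((20, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            BART(np.ones(20), X).fit()

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(60, 3))
        y = X[:, 0] * 5 + rng.normal(0, 0.5, 60)
        cfg = BartConfig(n_trees=10, n_burn=20, n_post=30, seed=9)
        r1 = BART(y, X, config=cfg).fit()
        r2 = BART(y, X, config=cfg).fit()
        assert np.array_equal(r1.posterior.in_sample_scaled, r2.posterior.in_sample_scaled)
        assert np.array_equal(r1.posterior.sigma2, r2.posterior.sigma2)

    def test_shift_equivariance_exact(self):
        # the range transform absorbs an additive constant: same seed,
        # identical sampler path, all predictions shift by c
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(80, 3))
        y = 3.0 * X[:, 1] + rng.normal(0, 0.3, 80)
        cfg = BartConfig(n_trees=10, n_burn=30, n_post=40, seed=11)
        r1 = BART(y, X, config=cfg).fit()
        r2 = BART(y + 100.0, X, config=cfg).fit()
        assert np.allclose(r2.fitted_values, r1.fitted_values + 100.0, atol=1e-9)
        p1 = r1.partial_dependence(1)
        p2 = r2.partial_dependence(1)
        assert np.allclose(p2.mean, p1.mean + 100.0, atol=1e-9)

    def test_split_values_within_training_range(self, step_fit):
        X, _, res = step_fit
        for snaps in res.posterior.trees[:20]:
            for snap in snaps:
                for node, j in enumerate(snap.var):
                    if j >= 0:
                        assert X[:, j].min() <= snap.val[node] <= X[:, j].max()

    def test_sigma2_draws_positive(self, step_fit):
        _, _, res = step_fit
        assert (res.posterior.sigma2 > 0).all()


class TestPartialDependence:
    def test_eq3_brute_force_equivalence(self, step_fit):
        X, _, res = step_fit
        post = res.posterior
        pdp = res.partial_dependence(0)
        bf = np.zeros_like(pdp.draws)
        for i, snaps in enumerate(post.trees):
            for vi, v in enumerate(pdp.values):
                Xm = X.copy()
                Xm[:, 0] = v
                acc = np.zeros(len(X))
                for snap in snaps:
                    acc += _tree_predict(snap, Xm)
                bf[vi, i] = acc.mean()
        bf = post.to_original(bf)
        assert np.max(np.abs(bf - pdp.draws)) < 1e-9

    def test_irrelevant_feature_flat_pdp(self):
        post = _posterior([[_stump(0, 0.5, -0.5, 0.5)]], 0.0, 10.0, p=2)
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(30, 2))
        pdp = partial_dependence(post, X, 1)
        expected = 10.0 * (X[:, 0] >= 0.5).mean()
        assert np.allclose(pdp.mean, expected, atol=1e-12)

    def test_band_ordering_and_monotone_levels(self, step_fit):
        _, _, res = step_fit
        pdp = res.partial_dependence(0)
        assert (pdp.lower <= pdp.mean + 1e-12).all()
        assert (pdp.mean <= pdp.upper + 1e-12).all()
        lo80, hi80 = pdp.band(0.80)
        lo99, hi99 = pdp.band(0.99)
        assert (lo99 <= lo80 + 1e-12).all()
        assert (hi80 <= hi99 + 1e-12).all()

    def test_zero_inflated_feature_gets_exact_zero_evaluation(self):
        rng = np.random.default_rng(3)
        x0 = np.where(rng.uniform(size=200) < 0.7, 0.0, rng.uniform(1, 5, 200))
        X = np.column_stack([x0, rng.uniform(size=200)])
        y = 4.0 * (x0 > 0) + rng.normal(0, 0.5, 200)
        res = BART(y, X, config=BartConfig(n_trees=10, n_burn=30, n_post=50, seed=4)).fit()
        pdp = res.partial_dependence(0)
        assert 0.0 in pdp.values

    def test_constant_feature_single_point_with_warning(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(50), rng.uniform(size=50)])
        y = rng.normal(size=50)
        res = BART(y, X, config=BartConfig(n_trees=5, n_burn=10, n_post=10, seed=1)).fit()
        with pytest.warns(UserWarning, match="constant"):
            pdp = res.partial_dependence(0)
        assert len(pdp.values) == 1


class TestVip:
    def test_all_splits_on_one_variable(self):
        post = _posterior([[_stump(2, 0.5, -0.1, 0.1)]], 0.0, 1.0, p=4)
        post.split_counts[0, 2] = 1.0
        vip = variable_inclusion_proportions(post)
        assert vip.tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_no_splits_contribute_uniform(self):
        post = _posterior([[_leaf(0.0)]], 0.0, 1.0, p=4)
        assert np.allclose(variable_inclusion_proportions(post), 0.25)

    def test_normalization_and_top1_on_signal(self, step_fit):
        _, _, res = step_fit
        vip = res.variable_inclusion_proportions()
        assert vip.sum() == pytest.approx(1.0, abs=1e-9)
        assert vip.idxmax() == "x0"
        assert top_variables(res.posterior, 3).index[0] == "x0"


class TestModelApi:
    def test_from_dataframe_and_summary(self, step_fit):
        X, y, _ = step_fit
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        df["ld"] = y
        model = BART.from_dataframe(
            df, "ld", config=BartConfig(n_trees=5, n_burn=10, n_post=20, seed=2)
        )
        res = model.fit()
        text = res.summary()
        assert "Pseudo-R2" in text and "f0" in text
        assert res.model.feature_names == [f"f{j}" for j in range(X.shape[1])]

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10 observations"):
            BART(np.arange(5.0), np.ones((5, 1))).fit()


def test_posterior_roundtrip_through_archive(step_fit, tmp_path):
    from localdiff.bart import load_posterior, save_posterior

    X, y, res = step_fit
    path = tmp_path / "posterior.npz"
    save_posterior(path, res.posterior)
    back = load_posterior(path)
    assert back.feature_names == res.posterior.feature_names
    assert np.array_equal(back.sigma2, res.posterior.sigma2)
    Xq = X[:25]
    assert np.allclose(predict(back, Xq), predict(res.posterior, Xq), atol=1e-12)
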