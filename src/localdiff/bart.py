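"""Bayesian Additive Regression Trees (BART) for localized-difference inference.

A sum-of-trees regression y = sum_{t=1..m} g(x; T_t, M_t) + eps,
eps ~ N(0, sigma^2), sampled by Bayesian backfitting MCMC: each sweep
updates every tree against the partial residual of the other m-1 trees via
Metropolis-Hastings proposals (grow / prune / change) whose acceptance uses
the marginal likelihood under the conjugate normal leaf prior
N(0, sigma_mu^2) with sigma_mu = 0.5 / (k sqrt(m)) on the internally
range-scaled response; leaf means are then drawn from their conjugate
posteriors and sigma^2 from its scaled-inverse-chi^2(nu, lambda)
conditional, with lambda calibrated so that Pr(sigma^2 < sigma_hat^2) = q
for a least-squares estimate sigma_hat^2.  The tree-structure prior makes a
node at depth d internal with probability alpha (1+d)^(-beta).

Inference products follow the partial-dependence / variable-inclusion
toolkit: for a feature j, the partial dependence at value v is the average
over all n training rows of the prediction with x_j set to v, computed per
posterior draw so that a 95% credible band accompanies the mean curve;
variable inclusion proportions (VIP) are the across-draw average fraction
of split rules using each feature.

The public surface is a statsmodels-style pair: :class:`BART` (model,
built from arrays or a DataFrame) and :class:`BARTResults` (posterior,
diagnostics, prediction, PDP, VIP, summary table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BartConfig:
    """Sampler hyperparameters (standard sum-of-trees defaults)."""

    n_trees: int = 50
    n_burn: int = 250
    n_post: int = 1000
    k: float = 2.0
    nu: float = 3.0
    q: float = 0.9
    alpha: float = 0.95
    beta: float = 2.0
    p_grow: float = 0.28
    p_prune: float = 0.28
    p_change: float = 0.44
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.n_post < 1 or self.n_burn < 0:
            raise ValueError("n_trees >= 1, n_post >= 1, n_burn >= 0 required")
        if not (0.0 < self.alpha < 1.0) or self.beta < 0:
            raise ValueError("need alpha in (0,1) and beta >= 0")
        if self.nu <= 0 or not (0.0 < self.q < 1.0) or self.k <= 0:
            raise ValueError("need nu > 0, q in (0,1), k > 0")
        if abs(self.p_grow + self.p_prune + self.p_change - 1.0) > 1e-9:
            raise ValueError("proposal probabilities must sum to 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf >= 1 required")


class TreeSnapshot(NamedTuple):
    """Frozen tree: parallel node arrays; var < 0 marks a leaf."""

    var: np.ndarray
    val: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_value: np.ndarray


@dataclass
class BartPosterior:
    """Retained draws of the sum-of-trees sampler.

    ``trees[i]`` holds the m tree snapshots of retained iteration i;
    predictions of an iteration are the sum over its trees, de-scaled by
    the stored response transform.  ``sigma2`` is on the original response
    scale.
    """

    trees: list
    sigma2: np.ndarray
    y_min: float
    y_max: float
    feature_names: list
    in_sample_scaled: np.ndarray  # n_post x n
    split_counts: np.ndarray      # n_post x p
    config: BartConfig
    degenerate: bool = False

    @property
    def n_draws(self) -> int:
        return len(self.trees)

    @property
    def scale(self) -> float:
        return self.y_max - self.y_min if self.y_max > self.y_min else 1.0

    def to_original(self, scaled: np.ndarray) -> np.ndarray:
        if self.y_max == self.y_min:  # degenerate constant-response fit
            return np.asarray(scaled) + self.y_min
        return (scaled + 0.5) * self.scale + self.y_min

    @property
    def in_sample(self) -> np.ndarray:
        """Retained in-sample predictions on the original response scale."""
        return self.to_original(self.in_sample_scaled)


@dataclass
class PdpResult:
    """Partial-dependence curve with a posterior credible band.

    ``draws`` has shape (n_eval, n_draws); ``mean``, ``lower`` and
    ``upper`` are its across-draw mean and percentile band on the original
    response scale.  ``quantiles`` locate the evaluation values within the
    feature's empirical distribution.
    """

    feature: str
    values: np.ndarray
    quantiles: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray
    level: float = 0.95

    def band(self, level: float) -> tuple[np.ndarray, np.ndarray]:
        lo = (1.0 - level) / 2.0
        return (
            np.percentile(self.draws, 100 * lo, axis=1),
            np.percentile(self.draws, 100 * (1 - lo), axis=1),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "value": self.values,
                "quantile": self.quantiles,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.quantiles, self.lower, self.upper, alpha=0.25)
        ax.plot(self.quantiles, self.mean, **kwargs)
        ax.set_xlabel(f"{self.feature} (quantile)")
        ax.set_ylabel("partial dependence")
        return ax


# ---------------------------------------------------------------------------
# mutable tree used inside the sampler


class _Tree:
    __slots__ = ("var", "val", "left", "right", "parent", "depth", "leaf_value",
                 "node_of", "free")

    def __init__(self, n_obs: int):
        self.var = [-1]
        self.val = [0.0]
        self.left = [-1]
        self.right = [-1]
        self.parent = [-1]
        self.depth = [0]
        self.leaf_value = [0.0]
        self.node_of = np.zeros(n_obs, dtype=np.int32)
        self.free: list[int] = []

    def _alloc(self, parent: int) -> int:
        if self.free:
            i = self.free.pop()
            self.var[i] = -1
            self.val[i] = 0.0
            self.left[i] = self.right[i] = -1
            self.parent[i] = parent
            self.depth[i] = self.depth[parent] + 1
            self.leaf_value[i] = 0.0
            return i
        self.var.append(-1)
        self.val.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.parent.append(parent)
        self.depth.append(self.depth[parent] + 1)
        self.leaf_value.append(0.0)
        return len(self.var) - 1

    def leaf_ids(self) -> list[int]:
        free = set(self.free)
        return [i for i, v in enumerate(self.var) if v < 0 and i not in free]

    def singly_internal(self) -> list[int]:
        out = []
        for i, v in enumerate(self.var):
            if v >= 0 and self.var[self.left[i]] < 0 and self.var[self.right[i]] < 0:
                out.append(i)
        return out

    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    def grow(self, leaf: int, j: int, cut: float, idx: np.ndarray, go_left: np.ndarray):
        li = self._alloc(leaf)
        ri = self._alloc(leaf)
        self.var[leaf] = j
        self.val[leaf] = cut
        self.left[leaf] = li
        self.right[leaf] = ri
        self.node_of[idx[go_left]] = li
        self.node_of[idx[~go_left]] = ri

    def prune(self, node: int):
        li, ri = self.left[node], self.right[node]
        member = (self.node_of == li) | (self.node_of == ri)
        self.node_of[member] = node
        for c in (li, ri):
            self.var[c] = -1
            self.left[c] = self.right[c] = -1
            self.free.append(c)
        self.var[node] = -1
        self.left[node] = self.right[node] = -1

    def snapshot(self) -> TreeSnapshot:
        return TreeSnapshot(
            np.array(self.var, dtype=np.int32),
            np.array(self.val, dtype=float),
            np.array(self.left, dtype=np.int32),
            np.array(self.right, dtype=np.int32),
            np.array(self.leaf_value, dtype=float),
        )


def _tree_predict(snap: TreeSnapshot, X: np.ndarray) -> np.ndarray:
    """Vectorized root-to-leaf traversal for every row of X."""
    n = X.shape[0]
    cur = np.zeros(n, dtype=np.int32)
    if snap.var[0] < 0:
        return np.full(n, snap.leaf_value[0])
    while True:
        idx = np.flatnonzero(snap.var[cur] >= 0)
        if idx.size == 0:
            break
        nodes = cur[idx]
        go_left = X[idx, snap.var[nodes]] < snap.val[nodes]
        cur[idx] = np.where(go_left, snap.left[nodes], snap.right[nodes])
    return snap.leaf_value[cur]


def _tree_uses_feature(snap: TreeSnapshot, j: int) -> bool:
    # freed nodes are reset to var = -1, so a simple scan is exact
    return bool(np.any(snap.var == j))


# ---------------------------------------------------------------------------
# sampler internals


def _log_marginal(c, s, sig2, sigmu2):
    """Log marginal likelihood contribution of one leaf with count c, residual sum s
    (constant terms common to numerator and denominator omitted)."""
    denom = sig2 + c * sigmu2
    return 0.5 * math.log(sig2 / denom) + sigmu2 * s * s / (2.0 * sig2 * denom)


def _eligible_vars(Xsub: np.ndarray) -> np.ndarray:
    return np.flatnonzero(Xsub.max(axis=0) > Xsub.min(axis=0))


def _p_split(depth: int, alpha: float, beta: float) -> float:
    return alpha * (1.0 + depth) ** (-beta)


def fit(X: np.ndarray, y: np.ndarray, config: BartConfig | None = None,
        feature_names: Sequence[str] | None = None, seed: int | None = None) -> BartPosterior:
    """Run the backfitting MCMC and return the retained posterior.

    ``X`` is n x p without missing values, ``y`` the response (n >= 10).
    A constant response short-circuits to a degenerate intercept-only
    posterior.
    """
    config = config or BartConfig()
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    feature_names = list(feature_names)
    if len(feature_names) != p:
        raise ValueError("feature_names length must match X columns")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported; impute or filter first")
    if n < 10:
        raise ValueError("need at least 10 observations")

    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        warnings.warn("constant response: returning degenerate intercept-only posterior")
        snap = TreeSnapshot(
            np.array([-1], dtype=np.int32), np.zeros(1), np.array([-1], dtype=np.int32),
            np.array([-1], dtype=np.int32), np.zeros(1),
        )
        trees = [[snap] * config.n_trees for _ in range(config.n_post)]
        return BartPosterior(
            trees=trees, sigma2=np.zeros(config.n_post), y_min=y_min, y_max=y_max,
            feature_names=feature_names,
            in_sample_scaled=np.zeros((config.n_post, n)),
            split_counts=np.zeros((config.n_post, p)),
            config=config, degenerate=True,
        )

    rng = np.random.default_rng(config.seed if seed is None else seed)
    scale = y_max - y_min
    ys = (y - y_min) / scale - 0.5

    m = config.n_trees
    sigmu2 = (0.5 / (config.k * math.sqrt(m))) ** 2
    # sigma_hat^2 from a least-squares fit (fall back to response variance)
    try:
        Xc = np.column_stack([np.ones(n), X])
        beta_hat, *_ = np.linalg.lstsq(Xc, ys, rcond=None)
        resid = ys - Xc @ beta_hat
        dof = max(n - min(n, p + 1), 1)
        sighat2 = float(resid @ resid / dof)
    except np.linalg.LinAlgError:  # pragma: no cover
        sighat2 = float(np.var(ys))
    if sighat2 <= 0:
        sighat2 = max(float(np.var(ys)), 1e-12)
    lam = sighat2 * stats.chi2.ppf(1.0 - config.q, config.nu) / config.nu
    sig2 = sighat2

    trees = [_Tree(n) for _ in range(m)]
    tree_fit = np.zeros((m, n))
    fit_all = np.zeros(n)
    min_leaf = config.min_leaf
    alpha, beta = config.alpha, config.beta

    kept_trees: list[list[TreeSnapshot]] = []
    kept_sig2 = np.empty(config.n_post)
    kept_fit = np.empty((config.n_post, n))
    kept_splits = np.zeros((config.n_post, p))

    for it in range(config.n_burn + config.n_post):
        for t, tree in enumerate(trees):
            R = ys - (fit_all - tree_fit[t])
            _update_tree_structure(tree, X, R, sig2, sigmu2, rng, config)
            # conjugate leaf-mean draws
            leaves = tree.leaf_ids()
            lookup = np.full(len(tree.var), -1, dtype=np.int32)
            lookup[leaves] = np.arange(len(leaves))
            cidx = lookup[tree.node_of]
            counts = np.bincount(cidx, minlength=len(leaves))
            sums = np.bincount(cidx, weights=R, minlength=len(leaves))
            post_var = sig2 * sigmu2 / (sig2 + counts * sigmu2)
            post_mean = sigmu2 * sums / (sig2 + counts * sigmu2)
            mu = post_mean + np.sqrt(post_var) * rng.standard_normal(len(leaves))
            for li, node in enumerate(leaves):
                tree.leaf_value[node] = mu[li]
            new_fit = mu[cidx]
            fit_all += new_fit - tree_fit[t]
            tree_fit[t] = new_fit
        e = ys - fit_all
        sig2 = (config.nu * lam + e @ e) / rng.chisquare(config.nu + n)

        if it >= config.n_burn:
            i = it - config.n_burn
            kept_trees.append([tree.snapshot() for tree in trees])
            kept_sig2[i] = sig2
            kept_fit[i] = fit_all
            free_sets = [set(tr.free) for tr in trees]
            for tr, fs in zip(trees, free_sets):
                for nd, v in enumerate(tr.var):
                    if v >= 0 and nd not in fs:
                        kept_splits[i, v] += 1

    return BartPosterior(
        trees=kept_trees,
        sigma2=kept_sig2 * scale * scale,
        y_min=y_min, y_max=y_max,
        feature_names=feature_names,
        in_sample_scaled=kept_fit,
        split_counts=kept_splits,
        config=config,
    )


def _update_tree_structure(tree: _Tree, X, R, sig2, sigmu2, rng, config: BartConfig):
    """One Metropolis-Hastings structure move (grow / prune / change)."""
    u = rng.random()
    if u < config.p_grow:
        _propose_grow(tree, X, R, sig2, sigmu2, rng, config)
    elif u < config.p_grow + config.p_prune:
        _propose_prune(tree, X, R, sig2, sigmu2, rng, config)
    else:
        _propose_change(tree, X, R, sig2, sigmu2, rng, config)


def _propose_grow(tree, X, R, sig2, sigmu2, rng, config):
    leaves = tree.leaf_ids()
    leaf = leaves[rng.integers(len(leaves))]
    idx = np.flatnonzero(tree.node_of == leaf)
    if idx.size < 2 * config.min_leaf:
        return
    Xsub = X[idx]
    eligible = _eligible_vars(Xsub)
    if eligible.size == 0:
        return
    j = int(eligible[rng.integers(eligible.size)])
    cuts = np.unique(Xsub[:, j])[1:]  # x < c goes left; smallest value can't cut
    cut = float(cuts[rng.integers(cuts.size)])
    go_left = Xsub[:, j] < cut
    nl = int(go_left.sum())
    nr = idx.size - nl
    if nl < config.min_leaf or nr < config.min_leaf:
        return
    Rsub = R[idx]
    sl = float(Rsub[go_left].sum())
    s = float(Rsub.sum())
    sr = s - sl
    log_ml = (
        _log_marginal(nl, sl, sig2, sigmu2)
        + _log_marginal(nr, sr, sig2, sigmu2)
        - _log_marginal(idx.size, s, sig2, sigmu2)
    )
    d = tree.depth[leaf]
    ps_d = _p_split(d, config.alpha, config.beta)
    ps_d1 = _p_split(d + 1, config.alpha, config.beta)
    log_prior = math.log(ps_d) + 2.0 * math.log(1.0 - ps_d1) - math.log(1.0 - ps_d)
    parent = tree.parent[leaf]
    sibling_leaf = (
        parent >= 0
        and tree.var[tree.left[parent] if tree.right[parent] == leaf else tree.right[parent]] < 0
    )
    n_si_after = len(tree.singly_internal()) + 1 - (1 if sibling_leaf else 0)
    # the uniform split-rule factor of the tree prior cancels the
    # variable/cutpoint terms of the proposal density, leaving only counts
    log_prop = (
        math.log(config.p_prune) - math.log(config.p_grow)
        + math.log(len(leaves)) - math.log(n_si_after)
    )
    if math.log(rng.random()) < log_ml + log_prior + log_prop:
        tree.grow(leaf, j, cut, idx, go_left)


def _propose_prune(tree, X, R, sig2, sigmu2, rng, config):
    si = tree.singly_internal()
    if not si:
        return
    node = si[rng.integers(len(si))]
    li, ri = tree.left[node], tree.right[node]
    in_l = tree.node_of == li
    in_r = tree.node_of == ri
    nl, nr = int(in_l.sum()), int(in_r.sum())
    sl, sr = float(R[in_l].sum()), float(R[in_r].sum())
    log_ml = (
        _log_marginal(nl + nr, sl + sr, sig2, sigmu2)
        - _log_marginal(nl, sl, sig2, sigmu2)
        - _log_marginal(nr, sr, sig2, sigmu2)
    )
    d = tree.depth[node]
    ps_d = _p_split(d, config.alpha, config.beta)
    ps_d1 = _p_split(d + 1, config.alpha, config.beta)
    log_prior = -(math.log(ps_d) + 2.0 * math.log(1.0 - ps_d1) - math.log(1.0 - ps_d))
    # reverse move regrows exactly the removed rule; its variable/cutpoint
    # density cancels against the rule factor of the tree prior
    n_leaves_after = tree.n_leaves() - 1
    log_prop = (
        math.log(config.p_grow) - math.log(config.p_prune)
        + math.log(len(si)) - math.log(n_leaves_after)
    )
    if math.log(rng.random()) < log_ml + log_prior + log_prop:
        tree.prune(node)


def _propose_change(tree, X, R, sig2, sigmu2, rng, config):
    si = tree.singly_internal()
    if not si:
        return
    node = si[rng.integers(len(si))]
    li, ri = tree.left[node], tree.right[node]
    idx = np.flatnonzero((tree.node_of == li) | (tree.node_of == ri))
    Xsub = X[idx]
    eligible = _eligible_vars(Xsub)
    if eligible.size == 0:
        return
    j_new = int(eligible[rng.integers(eligible.size)])
    cuts_new = np.unique(Xsub[:, j_new])[1:]
    cut_new = float(cuts_new[rng.integers(cuts_new.size)])
    go_left = Xsub[:, j_new] < cut_new
    nl_new = int(go_left.sum())
    nr_new = idx.size - nl_new
    if nl_new < config.min_leaf or nr_new < config.min_leaf:
        return
    Rsub = R[idx]
    in_l_old = tree.node_of[idx] == li
    sl_old = float(Rsub[in_l_old].sum())
    s = float(Rsub.sum())
    nl_old = int(in_l_old.sum())
    sl_new = float(Rsub[go_left].sum())
    log_ml = (
        _log_marginal(nl_new, sl_new, sig2, sigmu2)
        + _log_marginal(nr_new, s - sl_new, sig2, sigmu2)
        - _log_marginal(nl_old, sl_old, sig2, sigmu2)
        - _log_marginal(idx.size - nl_old, s - sl_old, sig2, sigmu2)
    )
    # proposal and prior rule factors cancel exactly: accept on likelihood
    if math.log(rng.random()) < log_ml:
        tree.var[node] = j_new
        tree.val[node] = cut_new
        tree.node_of[idx[go_left]] = li
        tree.node_of[idx[~go_left]] = ri


# ---------------------------------------------------------------------------
# posterior products


def predict(posterior: BartPosterior, Xnew, feature_names=None, return_draws=False):
    """Posterior predictions at new rows (original response scale).

    Returns the across-draw mean, or ``(mean, draws)`` with draws of shape
    (n_draws, n_rows) when ``return_draws`` is set.  When ``Xnew`` is a
    DataFrame its columns are aligned to the training features; unknown or
    missing columns raise.
    """
    if isinstance(Xnew, pd.DataFrame):
        missing = set(posterior.feature_names) - set(Xnew.columns)
        extra = set(Xnew.columns) - set(posterior.feature_names)
        if missing or extra:
            raise ValueError(f"feature mismatch: missing {sorted(missing)}, unknown {sorted(extra)}")
        Xnew = Xnew[posterior.feature_names].to_numpy(dtype=float)
    else:
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.shape[1] != len(posterior.feature_names):
            raise ValueError("Xnew has wrong number of columns")
    draws = np.empty((posterior.n_draws, Xnew.shape[0]))
    for i, snaps in enumerate(posterior.trees):
        acc = np.zeros(Xnew.shape[0])
        for snap in snaps:
            acc += _tree_predict(snap, Xnew)
        draws[i] = acc
    draws = posterior.to_original(draws)
    mean = draws.mean(axis=0)
    return (mean, draws) if return_draws else mean


def default_eval_grid(xj: np.ndarray, quantiles=None, include_zero="auto"):
    """PDP evaluation values: feature percentiles 5..95 (step 5), plus the
    exact value 0 for zero-inflated features, where the presence/absence
    contrast at zero is the quantity of interest."""
    if quantiles is None:
        quantiles = np.arange(0.05, 0.951, 0.05)
    quantiles = np.asarray(quantiles, dtype=float)
    values = np.quantile(xj, quantiles)
    if include_zero == "auto":
        include_zero = bool((xj == 0).any() and (xj > 0).any())
    if include_zero and not np.any(values == 0.0):
        q0 = float((xj <= 0).mean())
        values = np.concatenate([[0.0], values])
        quantiles = np.concatenate([[q0], quantiles])
        order = np.argsort(values, kind="stable")
        values, quantiles = values[order], quantiles[order]
    # collapse duplicate evaluation values, keeping the first quantile label
    _, first = np.unique(values, return_index=True)
    first.sort()
    return values[first], quantiles[first]


def partial_dependence(
    posterior: BartPosterior, X, feature, eval_quantiles=None,
    eval_values=None, include_zero="auto", level: float = 0.95,
) -> PdpResult:
    """Friedman partial dependence of the fitted surface on one feature.

    For each evaluation value v, x_j is set to v in *all* n training rows
    and predictions are averaged over rows within each posterior draw; the
    curve and its credible band are the across-draw mean and percentiles.
    Trees that never split on j contribute a v-independent average, which
    is computed once per draw (numerically identical to the full loop).
    """
    if isinstance(X, pd.DataFrame):
        X = X[posterior.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if isinstance(feature, str):
        j = posterior.feature_names.index(feature)
        fname = feature
    else:
        j = int(feature)
        fname = posterior.feature_names[j]
    xj = X[:, j]
    if eval_values is not None:
        values = np.asarray(eval_values, dtype=float)
        quantiles = np.array([(xj <= v).mean() for v in values])
    else:
        values, quantiles = default_eval_grid(xj, eval_quantiles, include_zero)
        if values.size == 1:
            warnings.warn(f"feature {fname!r} is constant in training data; single-point PDP")

    n = X.shape[0]
    # stack the n rows once per evaluation value so each j-dependent tree
    # is traversed a single time per draw
    Xbig = np.tile(X, (values.size, 1))
    Xbig[:, j] = np.repeat(values, n)
    draws = np.zeros((values.size, posterior.n_draws))
    for i, snaps in enumerate(posterior.trees):
        base = 0.0
        for snap in snaps:
            if _tree_uses_feature(snap, j):
                draws[:, i] += _tree_predict(snap, Xbig).reshape(values.size, n).mean(axis=1)
            else:
                base += _tree_predict(snap, X).mean()
        draws[:, i] += base

    draws = posterior.to_original(draws)
    lo = (1.0 - level) / 2.0
    return PdpResult(
        feature=fname,
        values=values,
        quantiles=quantiles,
        mean=draws.mean(axis=1),
        lower=np.percentile(draws, 100 * lo, axis=1),
        upper=np.percentile(draws, 100 * (1 - lo), axis=1),
        draws=draws,
        level=level,
    )


def variable_inclusion_proportions(posterior: BartPosterior) -> pd.Series:
    """Average fraction of split rules using each feature.

    Per retained draw, split counts over all trees are normalized to
    proportions (a draw with zero splits anywhere contributes the uniform
    1/p); proportions are then averaged across draws and sum to 1.
    """
    counts = posterior.split_counts
    p = counts.shape[1]
    totals = counts.sum(axis=1)
    props = np.where(
        totals[:, None] > 0, counts / np.maximum(totals[:, None], 1.0), 1.0 / p
    )
    return pd.Series(props.mean(axis=0), index=posterior.feature_names, name="vip")


def top_variables(posterior: BartPosterior, k: int = 8) -> pd.Series:
    """The k features with the highest variable inclusion proportion."""
    return variable_inclusion_proportions(posterior).sort_values(ascending=False).head(k)


def pseudo_r2(posterior: BartPosterior, X, y) -> float:
    """1 - SSE/SST with SSE from posterior-mean in-sample predictions."""
    y = np.asarray(y, dtype=float)
    pred = predict(posterior, X)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    sse = float(((y - pred) ** 2).sum())
    return 1.0 - sse / sst


def nrmse(posterior: BartPosterior, X, y) -> float:
    """RMSE of posterior-mean predictions normalized by |mean(y)|.

    The absolute value applies to the mean, which can be negative (e.g.
    NO2 localized difference).  A zero mean makes the quantity undefined;
    infinity is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    pred = predict(posterior, X)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if y.mean() == 0.0:
        warnings.warn("mean(y) is zero; NRMSE undefined, returning inf")
        return math.inf
    return rmse / abs(float(y.mean()))


# ---------------------------------------------------------------------------
# model / results API


class BART:
    """Sum-of-trees regression model (fit with :meth:`fit`).

    Parameters
    ----------
    y : array-like, shape (n,)
        Response (e.g. localized difference of one pollutant).
    X : array-like or DataFrame, shape (n, p)
        Predictors without missing values.
    feature_names : sequence of str, optional
        Required when X is a bare array and names matter downstream.
    config : BartConfig, optional
    """

    def __init__(self, y, X, feature_names=None, config: BartConfig | None = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.exog = np.asarray(X, dtype=float)
        self.endog = np.asarray(y, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.config = config or BartConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, predictors=None,
                       config: BartConfig | None = None) -> "BART":
        predictors = [c for c in df.columns if c != response] if predictors is None else list(predictors)
        return cls(df[response], df[predictors], config=config)

    def fit(self, seed: int | None = None) -> "BARTResults":
        posterior = fit(self.exog, self.endog, self.config, self.feature_names, seed=seed)
        return BARTResults(self, posterior)


class BARTResults:
    """Fitted sum-of-trees posterior with inference products."""

    def __init__(self, model: BART, posterior: BartPosterior):
        self.model = model
        self.posterior = posterior

    @property
    def fitted_values(self) -> np.ndarray:
        return self.posterior.in_sample.mean(axis=0)

    @property
    def sigma_draws(self) -> np.ndarray:
        return np.sqrt(self.posterior.sigma2)

    @property
    def pseudo_r2(self) -> float:
        y, pred = self.model.endog, self.fitted_values
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0.0:
            return 0.0
        return 1.0 - float(((y - pred) ** 2).sum()) / sst

    @property
    def nrmse(self) -> float:
        y, pred = self.model.endog, self.fitted_values
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        if y.mean() == 0.0:
            warnings.warn("mean(y) is zero; NRMSE undefined, returning inf")
            return math.inf
        return rmse / abs(float(y.mean()))

    def predict(self, Xnew, return_draws: bool = False):
        return predict(self.posterior, Xnew, return_draws=return_draws)

    def partial_dependence(self, feature, **kwargs) -> PdpResult:
        return partial_dependence(self.posterior, self.model.exog, feature, **kwargs)

    def variable_inclusion_proportions(self) -> pd.Series:
        return variable_inclusion_proportions(self.posterior)

    def top_variables(self, k: int = 8) -> pd.Series:
        return top_variables(self.posterior, k)

    def summary(self) -> str:
        cfg = self.posterior.config
        sig = self.sigma_draws
        lines = [
            "Sum-of-trees regression (BART) results",
            "=" * 46,
            f"{'Observations:':<26}{len(self.model.endog):>20}",
            f"{'Predictors:':<26}{len(self.model.feature_names):>20}",
            f"{'Trees:':<26}{cfg.n_trees:>20}",
            f"{'Retained draws:':<26}{self.posterior.n_draws:>20}",
            f"{'Burn-in:':<26}{cfg.n_burn:>20}",
            f"{'Pseudo-R2:':<26}{self.pseudo_r2:>20.3f}",
            f"{'NRMSE:':<26}{self.nrmse:>20.3f}",
            f"{'sigma (post. mean):':<26}{sig.mean():>20.3f}",
            f"{'sigma 95% CI:':<26}"
            f"{'[%.3f, %.3f]' % (np.percentile(sig, 2.5), np.percentile(sig, 97.5)):>20}",
            "-" * 46,
            "Top variables by inclusion proportion:",
        ]
        for name, v in self.top_variables(8).items():
            lines.append(f"  {name:<32}{v:>10.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# posterior serialization


def save_posterior(path, posterior: BartPosterior) -> None:
    """Serialize a posterior to a single ``.npz`` archive.

    Layout: all tree node arrays are concatenated in draw-major, tree-minor
    order with ``tree_sizes`` (n_draws * m) recording node counts, plus the
    response transform, sigma^2 draws, split counts, in-sample fits and a
    JSON-encoded config.  ``load_posterior`` restores an equivalent object.
    """
    import dataclasses as _dc
    import json as _json

    sizes, var, val, left, right, leaf = [], [], [], [], [], []
    for snaps in posterior.trees:
        for snap in snaps:
            sizes.append(len(snap.var))
            var.append(snap.var)
            val.append(snap.val)
            left.append(snap.left)
            right.append(snap.right)
            leaf.append(snap.leaf_value)
    np.savez_compressed(
        path,
        tree_sizes=np.array(sizes, dtype=np.int64),
        node_var=np.concatenate(var),
        node_val=np.concatenate(val),
        node_left=np.concatenate(left),
        node_right=np.concatenate(right),
        node_leaf=np.concatenate(leaf),
        sigma2=posterior.sigma2,
        y_range=np.array([posterior.y_min, posterior.y_max]),
        in_sample_scaled=posterior.in_sample_scaled,
        split_counts=posterior.split_counts,
        feature_names=np.array(posterior.feature_names, dtype=object),
        config_json=np.array(_json.dumps(_dc.asdict(posterior.config))),
        degenerate=np.array(posterior.degenerate),
    )


def load_posterior(path) -> BartPosterior:
    """Inverse of :func:`save_posterior`."""
    import json as _json

    with np.load(path, allow_pickle=True) as z:
        config = BartConfig(**_json.loads(str(z["config_json"])))
        m = config.n_trees
        sizes = z["tree_sizes"]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        # materialize each member once; archive access decompresses per read
        var = z["node_var"].astype(np.int32)
        val = z["node_val"]
        left = z["node_left"].astype(np.int32)
        right = z["node_right"].astype(np.int32)
        leaf = z["node_leaf"]
        flat = []
        for i in range(len(sizes)):
            lo, hi = offsets[i], offsets[i + 1]
            flat.append(TreeSnapshot(var[lo:hi], val[lo:hi], left[lo:hi],
                                     right[lo:hi], leaf[lo:hi]))
        trees = [flat[i:i + m] for i in range(0, len(flat), m)]
        y_min, y_max = z["y_range"]
        return BartPosterior(
            trees=trees, sigma2=z["sigma2"], y_min=float(y_min), y_max=float(y_max),
            feature_names=list(z["feature_names"]),
            in_sample_scaled=z["in_sample_scaled"], split_counts=z["split_counts"],
            config=config, degenerate=bool(z["degenerate"]),
        )
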