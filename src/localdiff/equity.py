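"""Demographic analyses of localized difference (LD).

Two complementary views of how model-observation divergence accrues across
racial/ethnic groups:

* an aggregate population view — the distribution of LD weighted by each
  group's allocated per-cell population;
* an area view — BART fits of LD on neighborhood composition alone
  (Model A: total population + five racial/ethnic shares) and on
  composition plus the 21 known-local-source predictors (Model B).
  Attenuation of a demographic partial-dependence curve from A to B
  indicates that source proximity explains the demographic LD pattern.

Weighted quantiles use the left-continuous inverse of the weighted ECDF
with midpoint interpolation at exact crossings (documented convention;
with integer weights it reduces to ordinary quantiles of the
weight-expanded sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bart import BART, BartConfig, BARTResults, PdpResult
from .scene import SHARE_NAMES

DEMOGRAPHIC_PREDICTORS = ("pop",) + SHARE_NAMES


def weighted_quantile(x, weights, qs) -> np.ndarray:
    """Quantiles by left-continuous inverse weighted ECDF, midpoint at ties.

    For each q: the smallest x with F(x) >= q; when F hits q exactly at
    some x_i, the midpoint of x_i and the next distinct value is returned.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    keep = weights > 0
    x, weights = x[keep], weights[keep]
    if x.size == 0:
        raise ValueError("all weights are zero")
    order = np.argsort(x, kind="stable")
    x, weights = x[order], weights[order]
    cdf = np.cumsum(weights) / weights.sum()
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    out = np.empty(qs.size)
    for i, q in enumerate(qs):
        k = int(np.searchsorted(cdf, q, side="left"))
        k = min(k, x.size - 1)
        if np.isclose(cdf[k], q) and k + 1 < x.size:
            out[i] = 0.5 * (x[k] + x[k + 1])
        else:
            out[i] = x[k]
    return out


@dataclass
class GroupWeightedSummary:
    group: str
    q25: float
    median: float
    q75: float
    total_weight: float


def population_weighted_quantiles(
    ld: pd.Series, group_counts: pd.DataFrame, groups=None
) -> pd.DataFrame:
    """Population-weighted LD quartiles per racial/ethnic group.

    ``group_counts`` holds per-cell allocated population counts (columns
    ``count_<share name>`` from population allocation, or any non-negative
    weight columns); cells with zero weight are ignored; all-zero groups
    are omitted with a warning.  Returns a frame indexed by group with
    q25 / median / q75 / total_weight columns.
    """
    if groups is None:
        groups = [c for c in group_counts.columns if c.startswith("count_")]
    joined = group_counts.join(ld.rename("_ld"), how="inner")
    rows = []
    for g in groups:
        w = joined[g].to_numpy()
        if not (w > 0).any():
            warnings.warn(f"group {g!r} has zero total weight; omitted")
            continue
        q25, med, q75 = weighted_quantile(joined["_ld"].to_numpy(), w, [0.25, 0.5, 0.75])
        rows.append(
            GroupWeightedSummary(g.removeprefix("count_"), q25, med, q75, float(w.sum()))
        )
    return pd.DataFrame(
        [(r.group, r.q25, r.median, r.q75, r.total_weight) for r in rows],
        columns=["group", "q25", "median", "q75", "total_weight"],
    ).set_index("group")


@dataclass
class DemographicModelFit:
    """A fitted demographic BART model with PDPs for its demographic terms."""

    results: BARTResults
    pdps: dict  # predictor name -> PdpResult

    @property
    def pseudo_r2(self) -> float:
        return self.results.pseudo_r2


def _demographic_frame(pop, shares) -> pd.DataFrame:
    df = pd.DataFrame({"pop": np.asarray(pop, dtype=float)})
    shares = pd.DataFrame(shares)
    for name in SHARE_NAMES:
        df[name] = shares[name].to_numpy(dtype=float)
    return df


def fit_model_a(
    pop, shares, ld, config: BartConfig | None = None,
    pdp_features=DEMOGRAPHIC_PREDICTORS, seed=None,
) -> DemographicModelFit:
    """Model A: LD as a function of total population and the five shares."""
    X = _demographic_frame(pop, shares)
    res = BART(np.asarray(ld, dtype=float), X, config=config).fit(seed=seed)
    pdps = {f: res.partial_dependence(f) for f in pdp_features}
    return DemographicModelFit(res, pdps)


def fit_model_b(
    pop, shares, kls_matrix: pd.DataFrame, ld, config: BartConfig | None = None,
    pdp_features=DEMOGRAPHIC_PREDICTORS, eval_grids: dict | None = None, seed=None,
) -> DemographicModelFit:
    """Model B: LD on demographics plus the 21 KLS predictors.

    Demographic PDPs are evaluated on the grids in ``eval_grids`` (feature
    -> evaluation values, typically frozen from a Model A fit) so the A/B
    curves are numerically comparable.
    """
    X = _demographic_frame(pop, shares)
    kls = pd.DataFrame(kls_matrix).reset_index(drop=True)
    X = pd.concat([X.reset_index(drop=True), kls], axis=1)
    res = BART(np.asarray(ld, dtype=float), X, config=config).fit(seed=seed)
    pdps = {}
    for f in pdp_features:
        ev = eval_grids.get(f) if eval_grids else None
        pdps[f] = res.partial_dependence(f, eval_values=ev)
    return DemographicModelFit(res, pdps)


def fit_models_ab(
    pop, shares, kls_matrix, ld, config: BartConfig | None = None,
    pdp_features=DEMOGRAPHIC_PREDICTORS, seed=None,
) -> tuple[DemographicModelFit, DemographicModelFit]:
    """Fit Model A then Model B with B's demographic PDPs on A's grids."""
    a = fit_model_a(pop, shares, ld, config, pdp_features, seed=seed)
    grids = {f: p.values for f, p in a.pdps.items()}
    b = fit_model_b(pop, shares, kls_matrix, ld, config, pdp_features, grids, seed=seed)
    return a, b


@dataclass
class AttenuationReport:
    predictor: str
    range_a: float
    range_b: float
    difference: float  # range_b - range_a
    ratio: float       # range_b / range_a


def _pdp_range(pdp: PdpResult, q_lo=0.05, q_hi=0.95) -> float:
    inside = (pdp.quantiles >= q_lo - 1e-12) & (pdp.quantiles <= q_hi + 1e-12)
    if not inside.any():
        inside = np.ones(len(pdp.quantiles), dtype=bool)
    curve = pdp.mean[inside]
    return float(curve.max() - curve.min())


def pdp_attenuation(pdp_a: PdpResult, pdp_b: PdpResult, q_lo=0.05, q_hi=0.95) -> AttenuationReport:
    """Change in a demographic PDP's 5th-95th percentile range from A to B.

    A ratio below 1 means the demographic relationship weakens once local
    sources enter the model — the demographic LD pattern is (partly)
    explained by source proximity.
    """
    if pdp_a.feature != pdp_b.feature or not np.array_equal(pdp_a.values, pdp_b.values):
        raise ValueError("attenuation requires the same predictor and evaluation grid")
    ra = _pdp_range(pdp_a, q_lo, q_hi)
    rb = _pdp_range(pdp_b, q_lo, q_hi)
    ratio = rb / ra if ra > 0 else np.nan
    return AttenuationReport(pdp_a.feature, ra, rb, rb - ra, ratio)


def attenuation_table(fit_a: DemographicModelFit, fit_b: DemographicModelFit) -> pd.DataFrame:
    rows = []
    for f in fit_a.pdps:
        rep = pdp_attenuation(fit_a.pdps[f], fit_b.pdps[f])
        rows.append((rep.predictor, rep.range_a, rep.range_b, rep.difference, rep.ratio))
    return pd.DataFrame(
        rows, columns=["predictor", "range_a", "range_b", "difference", "ratio"]
    ).set_index("predictor")
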