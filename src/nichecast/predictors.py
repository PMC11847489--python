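"""Predictor reduction: correlation/VIF pruning then contribution pruning.

Collinearity is removed by the iterative rule: find the pair of variables
with the largest |Pearson r| at or above the threshold (default 0.7),
regress each member of the pair on all other currently-kept variables to
obtain its variance inflation factor VIF_i = 1/(1 − R²_i), and drop the
one with the larger VIF; repeat until no pair exceeds the threshold.
A second step fits a preliminary presence-background model several times
(differing background seeds) and drops variables whose mean percent
contribution falls at or below a cutoff (default 1 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maxent
from .raster import RasterStack


@dataclass
class CorrelationReport:
    variables: list[str]
    r_matrix: pd.DataFrame
    steps: list[dict] = field(default_factory=list)
    constant_vars: list[str] = field(default_factory=list)


@dataclass
class ContributionReport:
    per_run: pd.DataFrame       # runs × variables, percent contributions
    mean: pd.Series
    dropped: list[str]
    runs: int


def _shared_data_table(stack: RasterStack) -> pd.DataFrame:
    rows, cols = stack.data_cells()
    return stack.env_table(rows, cols)


def pairwise_correlation(stack: RasterStack) -> CorrelationReport:
    """Pearson correlations over cells where every layer has data.

    Constant layers yield undefined (NaN) correlations and are flagged.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers")
    tab = _shared_data_table(stack)
    if len(tab) < 3:
        raise ValueError("need at least 3 shared data cells")
    constant = [v for v in tab.columns if tab[v].nunique() <= 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = tab.corr(method="pearson")
    for v in tab.columns:
        r.loc[v, v] = 1.0
    return CorrelationReport(list(tab.columns), r, constant_vars=constant)


def _vif(tab: pd.DataFrame, target: str, others: list[str]) -> float:
    """VIF of ``target`` regressed on ``others`` (OLS, with intercept)."""
    if not others:
        return 1.0
    y = tab[target].to_numpy(float)
    X = np.column_stack([np.ones(len(tab))] + [tab[o].to_numpy(float) for o in others])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(1.0 / (1.0 - r2))


def vifcor_prune(stack: RasterStack, r_threshold: float = 0.7
                 ) -> tuple[list[str], CorrelationReport]:
    """Iteratively drop the higher-VIF member of the most-correlated pair.

    Ties on VIF drop the variable later in input order.  Perfect
    multicollinearity reports VIF = +inf for the offending variable.
    """
    report = pairwise_correlation(stack)
    tab = _shared_data_table(stack)
    kept = list(tab.columns)
    order = {v: i for i, v in enumerate(kept)}
    while True:
        r = tab[kept].corr(method="pearson").abs()
        np.fill_diagonal(r.values, 0.0)
        r = r.fillna(0.0)
        max_r = float(r.values.max()) if len(kept) > 1 else 0.0
        if max_r < r_threshold:
            break
        i, j = np.unravel_index(np.argmax(r.values), r.shape)
        a, b = r.index[i], r.columns[j]
        if order[a] > order[b]:
            a, b = b, a
        others = [v for v in kept if v not in (a, b)]
        vif_a = _vif(tab, a, others + [b])
        vif_b = _vif(tab, b, others + [a])
        # drop the larger VIF; tie -> the variable later in input order
        drop = b if (vif_b >= vif_a) else a
        report.steps.append({"pair": (a, b), "abs_r": max_r,
                             "vif": {a: vif_a, b: vif_b}, "dropped": drop})
        kept.remove(drop)
    report.r_matrix = tab[kept].corr(method="pearson") if len(kept) > 1 else report.r_matrix
    return kept, report


def contribution_prune(presence_env: pd.DataFrame, stack: RasterStack,
                       threshold_pct: float = 1.0, runs: int = 10,
                       seed: int | None = None, *, min_presences: int = 10,
                       background_max: int = 10000,
                       spec: maxent.FeatureSpec | None = None,
                       **fit_kwargs) -> tuple[list[str], ContributionReport]:
    """Drop variables whose mean percent contribution is at or below the cutoff.

    A preliminary model (default linear+quadratic+hinge, RM 1 — the
    conventional auto-feature choice at these sample sizes) is fitted
    ``runs`` times with differing background seeds; contributions are
    averaged over runs.
    """
    if len(presence_env) < min_presences:
        raise ValueError(f"need at least {min_presences} presences for contribution pruning")
    spec = spec or maxent.FeatureSpec("lqh", rm=1.0)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(runs):
        bg, _, _ = maxent.sample_background(stack, max_points=background_max,
                                           seed=int(rng.integers(2 ** 31)))
        model = maxent.fit(presence_env, bg, spec, **fit_kwargs)
        rows.append(maxent.percent_contribution(model, presence_env,
                                                **{k: v for k, v in fit_kwargs.items()
                                                   if k in ("max_iter", "tol")}))
    per_run = pd.DataFrame(rows).reset_index(drop=True)
    mean = per_run.mean()
    dropped = [v for v in mean.index if mean[v] <= threshold_pct]
    kept = [v for v in stack.names if v not in dropped]
    if not kept:
        raise ValueError("contribution pruning removed every variable; review the threshold")
    return kept, ContributionReport(per_run, mean, dropped, runs)
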