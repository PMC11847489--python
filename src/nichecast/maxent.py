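"""Presence-background maximum-entropy modelling.

The model is the Gibbs distribution q(x) ∝ exp(Σ_j λ_j f_j(x)) over the
background cells, where the features f_j expand the raw predictors into
linear, quadratic, pairwise-product and hinge terms, all scaled into
[0, 1] on the calibration data.  Coefficients minimize the L1-penalized
negative log-likelihood of the presences

    −(1/m) Σ_i η(x_i) + log Z_λ + Σ_j β_j |λ_j|,

with η(x) = Σ_j λ_j f_j(x) and Z_λ = Σ_background e^{η(x)}.  The penalty
weights follow the conventional per-feature-class schedule
β_j = RM · β_class(m) · s_j/√m (s_j = feature standard deviation over the
presences, m = number of presences), so a larger regularization
multiplier (RM) yields sparser, smoother models.  The optimizer works on
the split positive-part parameterization λ = λ⁺ − λ⁻ (bound-constrained
L-BFGS), which renders the penalized objective smooth and convex.

Outputs: the raw distribution q (sums to one over the background), and
the cloglog transform c(x) = 1 − exp(−e^H q(x)) with H the entropy of the
fitted raw distribution, an occurrence-probability-like score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

VALID_CLASSES = frozenset("lqph")

#: per-class regularization schedule: sample-size breakpoints -> beta values,
#: piecewise-linearly interpolated in the presence count and clamped at the
#: ends.  Linear/quadratic/product share one table; hinge has a 0.5 floor.
DEFAULT_BETA_SCHEDULE: dict[str, tuple[list[float], list[float]]] = {
    "lqp": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "h": ([0], [0.5]),
}


@dataclass(frozen=True)
class FeatureSpec:
    """Feature classes (subset of 'lqph') and regularization multiplier."""

    classes: str
    rm: float = 1.0

    def __post_init__(self) -> None:
        cls = "".join(sorted(set(self.classes)))
        if not cls or not set(cls) <= VALID_CLASSES:
            raise ValueError(f"classes must be a nonempty subset of 'lqph', got {self.classes!r}")
        object.__setattr__(self, "classes", cls)
        if self.rm <= 0:
            raise ValueError("regularization multiplier must be positive")


@dataclass(frozen=True)
class Feature:
    kind: str           # 'linear' | 'quadratic' | 'product' | 'hinge_fwd' | 'hinge_rev'
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def beta_class(self) -> str:
        return "h" if self.kind.startswith("hinge") else "lqp"


@dataclass
class FeatureMap:
    """Scaling bounds, hinge knots and the ordered feature list."""

    variables: list[str]
    mins: dict[str, float]
    maxs: dict[str, float]
    knots: dict[str, np.ndarray]
    features: list[Feature]
    constant_vars: list[str] = field(default_factory=list)

    def design_matrix(self, env: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Evaluate every feature on the rows of ``env`` (columns ∈ [0,1]).

        With ``clamp`` each variable is clipped to its calibration
        [min, max] before evaluation (used for scenario projection).
        """
        cols = {}
        for v in self.variables:
            x = np.asarray(env[v], dtype=float)
            if not np.all(np.isfinite(x)):
                bad = int(np.flatnonzero(~np.isfinite(x))[0])
                raise ValueError(f"non-finite value for variable {v!r} at row {bad}")
            if clamp:
                x = np.clip(x, self.mins[v], self.maxs[v])
            cols[v] = x
        n = len(env)
        out = np.empty((n, len(self.features)), dtype=float)
        scaled = {v: (cols[v] - self.mins[v]) / max(self.maxs[v] - self.mins[v], 1e-300)
                  if v not in self.constant_vars else np.zeros(n)
                  for v in self.variables}
        for j, f in enumerate(self.features):
            if f.kind == "linear":
                out[:, j] = scaled[f.variables[0]]
            elif f.kind == "quadratic":
                out[:, j] = scaled[f.variables[0]] ** 2
            elif f.kind == "product":
                out[:, j] = scaled[f.variables[0]] * scaled[f.variables[1]]
            elif f.kind == "hinge_fwd":
                v = f.variables[0]
                out[:, j] = np.clip((cols[v] - f.knot) / (self.maxs[v] - f.knot), 0.0, 1.0)
            elif f.kind == "hinge_rev":
                v = f.variables[0]
                out[:, j] = np.clip((f.knot - cols[v]) / (f.knot - self.mins[v]), 0.0, 1.0)
            else:  # pragma: no cover
                raise AssertionError(f.kind)
        return out


def build_feature_map(background_env: pd.DataFrame, classes: str,
                      n_knots: int = 50) -> FeatureMap:
    """Derive scaling bounds and hinge knots from the background sample.

    Hinge knots sit at interior background quantiles (``n_knots`` per
    direction per variable).  Constant variables contribute only a
    constant-zero linear feature and are flagged.
    """
    spec = FeatureSpec(classes)
    variables = list(background_env.columns)
    if background_env.empty:
        raise ValueError("background sample is empty")
    mins, maxs, knots = {}, {}, {}
    constant = []
    for v in variables:
        x = np.asarray(background_env[v], dtype=float)
        mins[v], maxs[v] = float(np.min(x)), float(np.max(x))
        if mins[v] == maxs[v]:
            constant.append(v)
            knots[v] = np.empty(0)
            continue
        qs = (np.arange(n_knots) + 0.5) / n_knots
        k = np.unique(np.quantile(x, qs))
        k = k[(k > mins[v]) & (k < maxs[v])]
        knots[v] = k

    features: list[Feature] = []
    live = [v for v in variables if v not in constant]
    if "l" in spec.classes:
        features += [Feature("linear", (v,)) for v in variables]
    if "q" in spec.classes:
        features += [Feature("quadratic", (v,)) for v in live]
    if "p" in spec.classes:
        features += [Feature("product", (a, b))
                     for i, a in enumerate(live) for b in live[i + 1:]]
    if "h" in spec.classes:
        for v in live:
            features += [Feature("hinge_fwd", (v,), float(k)) for k in knots[v]]
            features += [Feature("hinge_rev", (v,), float(k)) for k in knots[v]]
    return FeatureMap(variables, mins, maxs, knots, features, constant)


def _beta_class_value(schedule_key: str, m: int,
                      schedule: dict | None = None) -> float:
    table = (schedule or DEFAULT_BETA_SCHEDULE)[schedule_key]
    return float(np.interp(m, table[0], table[1]))


def feature_penalties(fmap: FeatureMap, F_pres: np.ndarray, F_bg: np.ndarray,
                      rm: float, schedule: dict | None = None) -> np.ndarray:
    """β_j = rm · β_class(m) · s_j/√m with background-sd fallback."""
    m = F_pres.shape[0]
    s = F_pres.std(axis=0)
    s_bg = F_bg.std(axis=0)
    s = np.where(s > 0, s, np.where(s_bg > 0, s_bg, 1.0))
    cls = np.array([_beta_class_value(f.beta_class, m, schedule) for f in fmap.features])
    return rm * cls * s / np.sqrt(m)


@dataclass
class MaxEntModel:
    """A fitted penalized Gibbs model over a background sample."""

    feature_map: FeatureMap
    spec: FeatureSpec
    lambdas: np.ndarray
    betas: np.ndarray
    log_normalizer: float          # log Z over the background sample
    entropy: float                 # H of the fitted raw distribution
    background_env: pd.DataFrame   # the background cells used
    n_presences: int
    reg_gain: float                # regularized training gain vs uniform
    converged: bool = True

    @property
    def variables(self) -> list[str]:
        return self.feature_map.variables

    def eta(self, env: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        return self.feature_map.design_matrix(env, clamp=clamp) @ self.lambdas

    def raw(self, env: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Raw output q(x) = e^{η(x)}/Z; sums to 1 over the background."""
        return np.exp(self.eta(env, clamp=clamp) - self.log_normalizer)

    def cloglog(self, env: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """cloglog output 1 − exp(−e^H q(x)) ∈ [0, 1]."""
        return 1.0 - np.exp(-np.exp(self.entropy) * self.raw(env, clamp=clamp))

    def to_dict(self) -> dict:
        fm = self.feature_map
        return {
            "classes": self.spec.classes, "rm": self.spec.rm,
            "variables": fm.variables, "mins": fm.mins, "maxs": fm.maxs,
            "knots": {v: list(map(float, k)) for v, k in fm.knots.items()},
            "features": [{"kind": f.kind, "variables": list(f.variables), "knot": f.knot}
                         for f in fm.features],
            "lambdas": self.lambdas.tolist(), "betas": self.betas.tolist(),
            "log_normalizer": self.log_normalizer, "entropy": self.entropy,
            "n_presences": self.n_presences, "reg_gain": self.reg_gain,
        }


def _objective_terms(lam: np.ndarray, F_pres: np.ndarray, F_bg: np.ndarray):
    eta_bg = F_bg @ lam
    logZ = logsumexp(eta_bg)
    nll = -float(F_pres.mean(axis=0) @ lam) + logZ
    p = np.exp(eta_bg - logZ)
    grad = -F_pres.mean(axis=0) + p @ F_bg
    return nll, grad, logZ, p


def fit(presence_env: pd.DataFrame, background_env: pd.DataFrame, spec: FeatureSpec,
        *, max_iter: int = 500, tol: float = 1e-5, n_knots: int = 50,
        feature_map: FeatureMap | None = None,
        beta_schedule: dict | None = None) -> MaxEntModel:
    """Fit the penalized maximum-entropy model.

    ``tol`` is the convergence threshold on relative objective
    improvement; ``max_iter`` caps optimizer iterations.
    """
    if len(presence_env) < 2:
        raise ValueError("need at least 2 presence records")
    if presence_env.drop_duplicates().shape[0] < 2:
        raise ValueError("need at least 2 distinct presence records")
    fmap = feature_map or build_feature_map(background_env, spec.classes, n_knots=n_knots)
    F_pres = fmap.design_matrix(presence_env)
    F_bg = fmap.design_matrix(background_env)
    beta = feature_penalties(fmap, F_pres, F_bg, spec.rm, beta_schedule)
    J = F_pres.shape[1]

    def f_and_g(theta: np.ndarray):
        lam = theta[:J] - theta[J:]
        nll, grad, _, _ = _objective_terms(lam, F_pres, F_bg)
        val = nll + float(beta @ (theta[:J] + theta[J:]))
        g = np.concatenate([grad + beta, -grad + beta])
        return val, g

    res = minimize(f_and_g, np.zeros(2 * J), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * J),
                   options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-8,
                            "maxfun": max_iter * 40})
    theta = res.x
    lam = theta[:J] - theta[J:]
    lam[np.abs(lam) < 1e-12] = 0.0
    nll, _, logZ, p = _objective_terms(lam, F_pres, F_bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    n_bg = F_bg.shape[0]
    penalty = float(beta @ np.abs(lam))
    reg_gain = -nll - penalty + np.log(n_bg)
    return MaxEntModel(fmap, spec, lam, beta, float(logZ), H, background_env,
                       len(presence_env), float(reg_gain), converged=bool(res.success))


def sample_background(stack, max_points: int = 10000, seed: int | None = None,
                      ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Uniform sample (without replacement) of data cells in a stack.

    Presence cells are not excluded.  Returns the environmental table and
    the sampled row/col indices.
    """
    rows, cols = stack.data_cells()
    n = len(rows)
    if n == 0:
        raise ValueError("stack has no data cells to sample background from")
    rng = np.random.default_rng(seed)
    take = rng.choice(n, size=min(max_points, n), replace=False)
    take.sort()
    return stack.env_table(rows[take], cols[take]), rows[take], cols[take]


def auc(scores_presence: Iterable[float], scores_background: Iterable[float]) -> float:
    """Mann–Whitney AUC: P(pres > bg) + ½ P(pres = bg)."""
    sp = np.asarray(list(scores_presence), dtype=float)
    sb = np.asarray(list(scores_background), dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2
    return float(u / (sp.size * sb.size))


def training_auc(model: MaxEntModel, presence_env: pd.DataFrame) -> float:
    return auc(model.raw(presence_env), model.raw(model.background_env))


# ---------------------------------------------------------------------------
# variable importance


def _features_without(fmap: FeatureMap, variable: str) -> FeatureMap:
    feats = [f for f in fmap.features if variable not in f.variables]
    return FeatureMap(fmap.variables, fmap.mins, fmap.maxs, fmap.knots, feats,
                      fmap.constant_vars)


def _features_only(fmap: FeatureMap, variable: str) -> FeatureMap:
    feats = [f for f in fmap.features if f.variables == (variable,)]
    return FeatureMap(fmap.variables, fmap.mins, fmap.maxs, fmap.knots, feats,
                      fmap.constant_vars)


def percent_contribution(model: MaxEntModel, presence_env: pd.DataFrame,
                         *, max_iter: int = 500, tol: float = 1e-5) -> pd.Series:
    """Per-variable contribution: normalized refit-drop in regularized gain.

    For each variable the model is refit with all of that variable's
    features removed; the drop in regularized training gain (clipped at
    zero) is normalized so contributions sum to 100.
    """
    variables = model.variables
    if len(variables) == 1:
        return pd.Series({variables[0]: 100.0})
    drops = {}
    for v in variables:
        sub = fit(presence_env, model.background_env, model.spec,
                  max_iter=max_iter, tol=tol,
                  feature_map=_features_without(model.feature_map, v))
        drops[v] = max(0.0, model.reg_gain - sub.reg_gain)
    total = sum(drops.values())
    if total == 0:
        return pd.Series({v: 100.0 / len(variables) for v in variables})
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()})


def permutation_importance(model: MaxEntModel, presence_env: pd.DataFrame,
                           background_env: pd.DataFrame | None = None,
                           seed: int | None = None) -> pd.Series:
    """Normalized drop in training AUC after shuffling one variable."""
    bg = background_env if background_env is not None else model.background_env
    rng = np.random.default_rng(seed)
    pooled = pd.concat([presence_env, bg], ignore_index=True)
    m = len(presence_env)
    base = auc(model.raw(presence_env), model.raw(bg))
    drops = {}
    for v in model.variables:
        shuffled = pooled.copy()
        shuffled[v] = rng.permutation(shuffled[v].to_numpy())
        scores = model.raw(shuffled)
        drops[v] = max(0.0, base - auc(scores[:m], scores[m:]))
    total = sum(drops.values())
    if total == 0:
        n = len(model.variables)
        return pd.Series({v: 100.0 / n for v in model.variables})
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()})


def jackknife_gains(presence_env: pd.DataFrame, background_env: pd.DataFrame,
                    spec: FeatureSpec, *, max_iter: int = 500, tol: float = 1e-5,
                    n_knots: int = 50) -> pd.DataFrame:
    """Leave-one-variable-out / single-variable gains and training AUCs."""
    if presence_env.shape[1] < 2:
        raise ValueError("jackknife needs at least 2 variables")
    fmap = build_feature_map(background_env, spec.classes, n_knots=n_knots)
    rows = []
    for v in fmap.variables:
        row: dict = {"variable": v}
        for label, sub_map in [("without", _features_without(fmap, v)),
                               ("only", _features_only(fmap, v))]:
            try:
                m = fit(presence_env, background_env, spec, max_iter=max_iter,
                        tol=tol, feature_map=sub_map)
                row[f"gain_{label}"] = m.reg_gain
                row[f"auc_{label}"] = training_auc(m, presence_env)
                row[f"failed_{label}"] = False
            except Exception:
                row[f"gain_{label}"] = np.nan
                row[f"auc_{label}"] = np.nan
                row[f"failed_{label}"] = True
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def response_curve(models: MaxEntModel | Sequence[MaxEntModel], variable: str,
                   n_points: int = 100) -> pd.DataFrame:
    """Mean (± sd over replicates) cloglog response to one variable.

    The variable sweeps its calibration range on an even grid; all other
    variables are held at their background means.
    """
    if isinstance(models, MaxEntModel):
        models = [models]
    ref = models[0]
    if variable not in ref.variables:
        raise KeyError(f"variable {variable!r} not in model")
    fm = ref.feature_map
    grid = np.linspace(fm.mins[variable], fm.maxs[variable], n_points)
    means = ref.background_env.mean()
    env = pd.DataFrame({v: np.full(n_points, means[v]) for v in ref.variables})
    env[variable] = grid
    preds = np.stack([m.cloglog(env) for m in models])
    return pd.DataFrame({"value": grid, "mean": preds.mean(axis=0),
                         "sd": preds.std(axis=0)})


# ---------------------------------------------------------------------------
# bootstrap replicates


@dataclass
class ReplicateSet:
    """Bootstrap replicates of a model sharing one background sample."""

    models: list[MaxEntModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("need at least one successful replicate")

    def cloglog_stats(self, env: pd.DataFrame, clamp: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
        preds = np.stack([m.cloglog(env, clamp=clamp) for m in self.models])
        return preds.mean(axis=0), preds.std(axis=0)

    @property
    def mean_entropy(self) -> float:
        return float(np.mean([m.entropy for m in self.models]))


def replicate_fit(presence_env: pd.DataFrame, background_env: pd.DataFrame,
                  spec: FeatureSpec, n: int = 10, seed: int | None = None,
                  **fit_kwargs) -> ReplicateSet:
    """Fit ``n`` bootstrap replicates (presences resampled with replacement,
    background fixed)."""
    rng = np.random.default_rng(seed)
    fmap = fit_kwargs.pop("feature_map", None) or build_feature_map(
        background_env, spec.classes, n_knots=fit_kwargs.pop("n_knots", 50))
    models = []
    errors = []
    for _ in range(n):
        idx = rng.integers(0, len(presence_env), size=len(presence_env))
        boot = presence_env.iloc[idx].reset_index(drop=True)
        try:
            models.append(fit(boot, background_env, spec, feature_map=fmap, **fit_kwargs))
        except Exception as e:  # noqa: BLE001 - per-replicate isolation
            errors.append(e)
    if not models:
        raise RuntimeError(f"all {n} replicates failed; first error: {errors[0]}")
    return ReplicateSet(models)
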