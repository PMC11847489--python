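"""Candidate-model grid search and three-criterion selection.

Candidates are the cross product of regularization multipliers with every
nonempty subset of the feature classes.  Each candidate is fitted on a
70/30 occurrence split and screened by (1) partial-ROC significance,
(2) omission rate at tolerance E, and (3) ΔAICc ≤ 2, where the ΔAICc
reference pool contains only candidates already passing the first two
criteria.  The selected specification is then refit on all occurrences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maxent
from .maxent import FeatureSpec, MaxEntModel


@dataclass(frozen=True)
class CandidateSpec:
    spec: FeatureSpec

    @property
    def label(self) -> str:
        return f"M_{self.spec.rm:g}_F_{self.spec.classes}_Set_1"


@dataclass
class SelectionCriteria:
    alpha: float = 0.05
    E: float = 0.05
    d_aicc_max: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 <= self.E < 1:
            raise ValueError("E must be in [0,1)")


@dataclass
class CandidateResult:
    spec: FeatureSpec
    label: str
    mean_auc_ratio: float = np.nan
    p_value: float = np.nan
    omission_rate: float = np.nan
    aicc: float = np.nan
    delta_aicc: float = np.nan
    n_nonzero: int = 0
    significant: bool = False
    meets_omission: bool = False
    meets_aicc: bool = False
    selected: bool = False
    failed: bool = False


DEFAULT_RM_VALUES = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_CLASSES = "lqph"


def generate_candidates(rm_values=DEFAULT_RM_VALUES,
                        classes: str = DEFAULT_CLASSES) -> list[CandidateSpec]:
    """Cross product of RM values with all nonempty feature-class subsets."""
    rm_values = list(rm_values)
    if not rm_values:
        raise ValueError("rm_values must be nonempty")
    base = list(dict.fromkeys(classes))
    if not base:
        raise ValueError("feature-class set must be nonempty")
    combos = ["".join(c) for n in range(1, len(base) + 1)
              for c in itertools.combinations(base, n)]
    return [CandidateSpec(FeatureSpec(c, rm=float(rm)))
            for rm in rm_values for c in combos]


def split_occurrences(table: pd.DataFrame, train_frac: float = 0.7,
                      seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test split with |train| = round(frac·n)."""
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"train_frac={train_frac} leaves an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (table.iloc[np.sort(perm[:n_train])].reset_index(drop=True),
            table.iloc[np.sort(perm[n_train:])].reset_index(drop=True))


def _tau(train_scores: np.ndarray, E: float) -> float:
    """Omission threshold: the ⌈E·n⌉-th smallest training score (min at E=0)."""
    s = np.sort(np.asarray(train_scores, float))
    k = int(np.ceil(E * len(s)))
    return float(s[0] if k == 0 else s[k - 1])


def omission_rate(train_scores, test_scores, E: float = 0.05) -> float:
    """Fraction of test presences scoring strictly below the E-threshold."""
    train_scores = np.asarray(train_scores, float)
    test_scores = np.asarray(test_scores, float)
    if train_scores.size == 0 or test_scores.size == 0:
        raise ValueError("train and test score sets must be nonempty")
    tau = _tau(train_scores, E)
    return float(np.mean(test_scores < tau))


def partial_roc(test_scores, raster_values, E: float = 0.05,
                iterations: int = 500, bootstrap_frac: float = 0.5,
                seed: int | None = None, max_thresholds: int = 1000
                ) -> tuple[float, float]:
    """Partial-ROC AUC ratio and its bootstrap p-value.

    Per iteration, ⌈frac·n⌉ test scores are resampled with replacement;
    over a descending threshold sweep the (proportion-of-area-predicted,
    sensitivity) curve is integrated on the region sensitivity ≥ 1−E and
    divided by the corresponding area under the 1:1 null line.  The
    p-value is the fraction of iterations with ratio ≤ 1.
    """
    test = np.asarray(test_scores, float)
    vals = np.asarray(raster_values, float)
    if test.size == 0:
        raise ValueError("test scores must be nonempty")
    uniq = np.unique(vals)
    if uniq.size < 2:
        warnings.warn("constant prediction raster: partial ROC undefined")
        return np.nan, 1.0
    if uniq.size > max_thresholds:
        thresholds = np.unique(np.quantile(vals, np.linspace(0, 1, max_thresholds)))
    else:
        thresholds = uniq
    # fraction of raster area predicted present at each threshold (score >= t)
    area_frac = 1.0 - np.searchsorted(np.sort(vals), thresholds, side="left") / vals.size
    rng = np.random.default_rng(seed)
    m = int(np.ceil(bootstrap_frac * test.size))
    ratios = np.empty(iterations)
    order = np.argsort(area_frac)
    af = area_frac[order]
    thr = thresholds[order]
    for it in range(iterations):
        sample = test[rng.integers(0, test.size, size=m)]
        sens = 1.0 - np.searchsorted(np.sort(sample), thr, side="left") / m
        keep = sens >= 1.0 - E
        if keep.sum() < 2:
            ratios[it] = np.nan
            continue
        x, y = af[keep], sens[keep]
        model_area = np.trapezoid(y, x)
        null_area = np.trapezoid(x, x)
        ratios[it] = model_area / null_area if null_area > 0 else np.nan
    valid = ratios[np.isfinite(ratios)]
    if valid.size == 0:
        return np.nan, 1.0
    return float(valid.mean()), float(np.mean(valid <= 1.0))


def aicc(model: MaxEntModel, occurrence_env: pd.DataFrame,
         all_cells_env: pd.DataFrame) -> float:
    """Small-sample-corrected AIC from standardized raw scores.

    k counts nonzero coefficients; raw scores are standardized to sum to
    one over all calibration-area data cells; undefined (NaN) when
    n ≤ k + 1.
    """
    k = int(np.count_nonzero(model.lambdas))
    n = len(occurrence_env)
    eta_all = model.eta(all_cells_env)
    eta_occ = model.eta(occurrence_env)
    from scipy.special import logsumexp
    log_norm = logsumexp(eta_all)
    lnl = float(np.sum(eta_occ - log_norm))
    if n <= k + 1:
        return np.nan
    return 2 * k - 2 * lnl + (2 * k * (k + 1)) / (n - k - 1)


def evaluate_candidates(cands: list[CandidateSpec], train_env: pd.DataFrame,
                        test_env: pd.DataFrame, background_env: pd.DataFrame,
                        all_cells_env: pd.DataFrame,
                        criteria: SelectionCriteria | None = None,
                        seed: int | None = None, *, proc_iterations: int = 500,
                        **fit_kwargs) -> list[CandidateResult]:
    """Fit and screen every candidate; flag the selected one(s).

    ``all_cells_env`` is the environment at every calibration-area data
    cell (used both as the partial-ROC prediction domain and the AICc
    standardization domain).
    """
    if not cands:
        raise ValueError("no candidate specs")
    criteria = criteria or SelectionCriteria()
    rng = np.random.default_rng(seed)
    results: list[CandidateResult] = []
    for cand in cands:
        res = CandidateResult(cand.spec, cand.label)
        try:
            model = maxent.fit(train_env, background_env, cand.spec, **fit_kwargs)
            train_scores = model.cloglog(train_env)
            test_scores = model.cloglog(test_env)
            raster_scores = model.cloglog(all_cells_env)
            res.omission_rate = omission_rate(train_scores, test_scores, criteria.E)
            res.mean_auc_ratio, res.p_value = partial_roc(
                test_scores, raster_scores, E=criteria.E,
                iterations=proc_iterations, seed=int(rng.integers(2 ** 31)))
            res.aicc = aicc(model, pd.concat([train_env, test_env], ignore_index=True),
                            all_cells_env)
            res.n_nonzero = int(np.count_nonzero(model.lambdas))
            res.significant = bool(res.p_value <= criteria.alpha)
            res.meets_omission = bool(res.omission_rate <= criteria.E)
        except Exception as e:  # noqa: BLE001 - per-candidate isolation
            res.failed = True
            warnings.warn(f"candidate {cand.label} failed: {e}")
        results.append(res)

    pool = [r for r in results
            if not r.failed and r.significant and r.meets_omission and np.isfinite(r.aicc)]
    if pool:
        best = min(r.aicc for r in pool)
        for r in results:
            if not r.failed and np.isfinite(r.aicc):
                r.delta_aicc = r.aicc - best
        for r in pool:
            r.meets_aicc = bool(r.delta_aicc <= criteria.d_aicc_max)
            r.selected = r.meets_aicc
    if not any(r.selected for r in results):
        warnings.warn("no candidate met all three selection criteria")
    return results


def results_table(results: list[CandidateResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model": r.label, "classes": r.spec.classes, "rm": r.spec.rm,
        "mean_auc_ratio": r.mean_auc_ratio, "p_value": r.p_value,
        "omission_rate": r.omission_rate, "aicc": r.aicc,
        "delta_aicc": r.delta_aicc, "k": r.n_nonzero,
        "significant": r.significant, "meets_omission": r.meets_omission,
        "meets_aicc": r.meets_aicc, "selected": r.selected, "failed": r.failed,
    } for r in results])
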