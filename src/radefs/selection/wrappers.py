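"""Recursive feature elimination and tree-ensemble importance ranking."""

from __future__ import annotations

import warnings

import numpy as np

from ..classifiers import ClassifierSpec, make_estimator
from ..cohort import Cohort
from ..evaluation import task_labels
from .base import (
    SelectionRequest,
    SelectionResult,
    aggregate_runs,
    candidate_pool,
)

_STOCHASTIC_KINDS = ("rf", "xgb")


class CapabilityError(ValueError):
    """The base estimator exposes no importance vector."""


def _importances(estimator) -> np.ndarray:
    if hasattr(estimator, "coef_"):
        coef = np.atleast_2d(estimator.coef_)
        return np.sqrt((coef**2).sum(axis=0))
    if hasattr(estimator, "feature_importances_"):
        return np.asarray(estimator.feature_importances_, dtype=float)
    raise CapabilityError(
        f"estimator {type(estimator).__name__} provides no feature importance"
    )


def _check_estimator_spec(request: SelectionRequest) -> ClassifierSpec:
    est = request.estimator
    if not isinstance(est, ClassifierSpec):
        raise CapabilityError(
            "rfe/importance selection needs a ClassifierSpec estimator"
        )
    if est.kind in ("svm_sigmoid", "svm_rbf"):
        raise CapabilityError(
            f"{est.kind} exposes no importance vector for elimination"
        )
    return est


def _standardized_xy(cohort: Cohort, pool: list[str], task: str):
    idx = cohort.feature_index(pool)
    X = cohort.X[:, idx]
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    y, _ = task_labels(cohort.labels, task)
    classes = sorted(set(y.tolist()))
    y_codes = np.array([classes.index(v) for v in y])
    return (X - mu) / sd, y_codes


def _rfe_once(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, p: int, step_n: int,
    seed: int,
) -> list[int]:
    """One elimination pass; returns the surviving column indices."""
    remaining = list(range(X.shape[1]))
    spec = spec.with_seed(seed)
    while len(remaining) > p:
        est = make_estimator(spec, n_features=len(remaining), n_samples=len(X))
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            est.fit(X[:, remaining], y)
        imp = _importances(est)
        n_drop = min(step_n, len(remaining) - p)
        drop = np.argsort(imp, kind="stable")[:n_drop]
        for j in sorted(drop, reverse=True):
            remaining.pop(int(j))
    return remaining


def rfe_select(
    cohort: Cohort,
    request: SelectionRequest,
    step_n: int = 1,
    task: str = "three_class",
) -> SelectionResult:
    """Backward elimination of the ``step_n`` least-important features per
    round until ``p`` remain; stochastic estimators are replicated with
    frequency consensus, deterministic ones run once."""
    spec = _check_estimator_spec(request)
    pool = candidate_pool(cohort, request)
    if request.p == len(pool):  # identity selection
        return SelectionResult(request, list(pool), {n: 1.0 for n in pool})
    X, y = _standardized_xy(cohort, pool, task)
    stochastic = spec.kind in _STOCHASTIC_KINDS
    n_runs = request.runs if stochastic else 1
    master = np.random.default_rng(request.seed)
    subsets = []
    for _ in range(n_runs):
        seed = int(master.integers(2**31)) if stochastic else spec.seed
        cols = _rfe_once(X, y, spec, request.p, step_n, seed)
        subsets.append([pool[j] for j in cols])
    selected, freq = aggregate_runs(subsets, request.p)
    return SelectionResult(request, selected, freq,
                           trace=[{"runs": n_runs, "step_n": step_n}])


def importance_select(
    cohort: Cohort,
    request: SelectionRequest,
    task: str = "three_class",
) -> SelectionResult:
    """Top-p features by tree-ensemble importance, with replicate consensus."""
    if request.method not in ("rf_importance", "xgb_importance"):
        raise ValueError(f"not an importance method: {request.method!r}")
    est = request.estimator
    if not isinstance(est, ClassifierSpec) or est.kind not in _STOCHASTIC_KINDS:
        est = ClassifierSpec("rf" if request.method == "rf_importance" else "xgb")
    pool = candidate_pool(cohort, request)
    X, y = _standardized_xy(cohort, pool, task)
    master = np.random.default_rng(request.seed)
    subsets = []
    for _ in range(request.runs):
        seed = int(master.integers(2**31))
        model = make_estimator(est.with_seed(seed), n_features=X.shape[1],
                               n_samples=len(X))
        model.fit(X, y)
        imp = _importances(model)
        order = np.argsort(-imp, kind="stable")
        subsets.append([pool[j] for j in order[: request.p]])
    selected, freq = aggregate_runs(subsets, request.p)
    return SelectionResult(request, selected, freq,
                           trace=[{"runs": request.runs}])
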