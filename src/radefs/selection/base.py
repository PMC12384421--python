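"""Shared selection machinery: requests, results, consensus, fitness scoring.

The :class:`SubsetScorer` is the internal objective used by wrapper methods:
cross-validated balanced accuracy of a classifier restricted to a candidate
subset, on node-grouped folds of the training cohort (selection never sees
observations of a node that validation will see).  The default internal
estimator is a minimal closed-form LDA, fast enough for population-scale
genetic search; any :class:`~radefs.classifiers.ClassifierSpec` works too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..classifiers import ClassifierSpec, fit as fit_classifier
from ..cohort import Cohort
from ..evaluation import balanced_accuracy, task_labels
from ..preprocessing import ndf_filter

METHODS = ("ga", "sda", "rfe", "rf_importance", "xgb_importance")


@dataclass(frozen=True)
class SelectionRequest:
    """One selection job: method, internal estimator, target size, pool, seed."""

    method: str
    p: int
    estimator: ClassifierSpec | str = "lda_fast"
    ndf_only: bool = False
    runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.p < 2:
            raise ValueError("target subset size p must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class SelectionResult:
    """Consensus subset plus per-feature selection frequencies and diagnostics."""

    request: SelectionRequest
    selected: list[str]
    frequency: dict[str, float]
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.selected) != self.request.p:
            raise ValueError(
                f"selected {len(self.selected)} features, requested {self.request.p}"
            )


def candidate_pool(cohort: Cohort, request: SelectionRequest,
                   alpha: float = 0.05) -> list[str]:
    """The feature pool a request draws from: all features, or the NDF subset."""
    if request.ndf_only:
        pool = ndf_filter(cohort, alpha=alpha).ndf_names
    else:
        pool = list(cohort.manifest.names)
    if request.p > len(pool):
        raise ValueError(
            f"target size p={request.p} exceeds candidate pool size {len(pool)}"
        )
    return pool


def aggregate_runs(
    per_run_subsets: Sequence[Sequence[str]], p: int
) -> tuple[list[str], dict[str, float]]:
    """Selection-frequency consensus across replicate runs.

    Frequency = fraction of runs containing the feature; consensus = top-p by
    frequency, ties broken lexicographically by name.
    """
    if not per_run_subsets:
        raise ValueError("no runs to aggregate")
    n_runs = len(per_run_subsets)
    freq: dict[str, float] = {}
    for subset in per_run_subsets:
        for name in set(subset):
            freq[name] = freq.get(name, 0.0) + 1.0
    freq = {k: v / n_runs for k, v in freq.items()}
    ranked = sorted(freq, key=lambda n: (-freq[n], n))
    return ranked[:p], freq


# --------------------------------------------------------------------------
# internal fitness scoring


def _grouped_folds(node_ids: np.ndarray, y: np.ndarray, k: int,
                   seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Node-grouped, class-stratified fold index pairs over observations."""
    nodes = []
    node_cls = {}
    for nid, lab in zip(node_ids, y):
        if nid not in node_cls:
            node_cls[nid] = lab
            nodes.append(nid)
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    by_class: dict[str, list[str]] = {}
    for nid in sorted(nodes):
        by_class.setdefault(node_cls[nid], []).append(nid)
    for cls_nodes in by_class.values():
        order = rng.permutation(cls_nodes)
        for i, nid in enumerate(order):
            fold_of[nid] = i % k
    obs_fold = np.array([fold_of[nid] for nid in node_ids])
    return [
        (np.flatnonzero(obs_fold != f), np.flatnonzero(obs_fold == f))
        for f in range(k)
    ]


class _FastLDA:
    """Closed-form pooled-covariance LDA on a column subset.

    Gaussian discriminant with shared covariance and a small ridge for
    stability; orders of magnitude faster than estimator objects when called
    thousands of times inside a genetic search.
    """

    @staticmethod
    def fold_bacc(X, y_codes, n_classes, tr, va) -> float:
        Xtr, Xva = X[tr], X[va]
        ytr, yva = y_codes[tr], y_codes[va]
        p = Xtr.shape[1]
        means = np.empty((n_classes, p))
        Sw = np.zeros((p, p))
        priors = np.empty(n_classes)
        for c in range(n_classes):
            Xc = Xtr[ytr == c]
            if len(Xc) == 0:
                return float("nan")
            mu = Xc.mean(axis=0)
            means[c] = mu
            d = Xc - mu
            Sw += d.T @ d
            priors[c] = len(Xc) / len(Xtr)
        Sw /= max(len(Xtr) - n_classes, 1)
        Sw[np.diag_indices_from(Sw)] += 1e-6 * max(np.trace(Sw) / p, 1e-12)
        A = np.linalg.solve(Sw, means.T)  # p x K
        scores = Xva @ A - 0.5 * np.einsum("cp,pc->c", means, A) + np.log(priors)
        pred = np.argmax(scores, axis=1)
        recalls = [
            (pred[yva == c] == c).mean() for c in range(n_classes) if (yva == c).any()
        ]
        return float(np.mean(recalls))


class SubsetScorer:
    """Cross-validated BACC of an estimator on feature subsets, with caching."""

    def __init__(
        self,
        cohort: Cohort,
        pool: list[str],
        estimator: ClassifierSpec | str = "lda_fast",
        task: str = "three_class",
        cv: int = 3,
        seed: int = 0,
    ) -> None:
        self.pool = list(pool)
        idx = cohort.feature_index(self.pool)
        self.X = np.ascontiguousarray(cohort.X[:, idx])
        y, _ = task_labels(cohort.labels, task)
        self.classes = sorted(set(y.tolist()))
        self.y_codes = np.array([self.classes.index(v) for v in y])
        self.y = y
        self.estimator = estimator
        self.folds = _grouped_folds(cohort.node_ids, y, cv, seed)
        self._cache: dict[bytes, float] = {}

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def score_mask(self, mask: np.ndarray) -> float:
        """Mean CV balanced accuracy of the subset encoded by a boolean mask."""
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            raise ValueError("cannot score an empty subset")
        Xs = self.X[:, cols]
        vals = []
        for tr, va in self.folds:
            if self.estimator == "lda_fast":
                b = _FastLDA.fold_bacc(Xs, self.y_codes, len(self.classes), tr, va)
                if not np.isnan(b):
                    vals.append(b)
            else:
                model = fit_classifier(self.estimator, Xs[tr], self.y[tr])
                vals.append(balanced_accuracy(self.y[va], model.predict(Xs[va])))
        out = float(np.mean(vals)) if vals else 0.0
        self._cache[key] = out
        return out

    def score_names(self, names: Sequence[str]) -> float:
        mask = np.zeros(self.d, dtype=bool)
        lookup = {n: i for i, n in enumerate(self.pool)}
        for n in names:
            mask[lookup[n]] = True
        return self.score_mask(mask)


def select(cohort: Cohort, request: SelectionRequest,
           task: str = "three_class", **kwargs) -> SelectionResult:
    """Dispatch a selection request to its method implementation."""
    from .ga import ga_select
    from .sda import sda_select
    from .wrappers import importance_select, rfe_select

    if request.method == "ga":
        return ga_select(cohort, request, task=task, **kwargs)
    if request.method == "sda":
        return sda_select(cohort, request, task=task, **kwargs)
    if request.method == "rfe":
        return rfe_select(cohort, request, task=task, **kwargs)
    return importance_select(cohort, request, task=task, **kwargs)
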