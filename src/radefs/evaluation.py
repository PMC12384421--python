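"""Grouped-stratified cross-validation and the three evaluation metrics.

Metrics follow the conventions used throughout the package: balanced accuracy
is the macro-average of per-class recalls (for binary tasks this equals the
mean of sensitivity and specificity), F1 is binary against a designated
positive class or macro-averaged, and AUC is the rank-based (Mann–Whitney)
area, averaged one-vs-rest for multi-class scores.

Cross-validation folds partition *nodes*, never observations, so a node's
three phase scans stay on one side of every fold boundary; stratification
preserves the node-level class mix.  The default plan is 5 folds at seed 42.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, fit
from .cohort import Cohort, LABELS
from .preprocessing import fit_apply_standardizer

TASKS = ("reactive_vs_rest", "pathologic_vs_rest", "ecs_vs_rest", "three_class")


def task_labels(labels: np.ndarray, task: str) -> tuple[np.ndarray, str | None]:
    """Relabel 3-class labels for a task; returns (y, positive_class)."""
    if task == "three_class":
        return np.asarray(labels, dtype=object), None
    if not task.endswith("_vs_rest"):
        raise ValueError(f"unknown task {task!r}")
    pos = task[: -len("_vs_rest")]
    if pos not in LABELS:
        raise ValueError(f"unknown task {task!r}")
    y = np.where(np.asarray(labels, dtype=object) == pos, pos, "rest")
    return y.astype(object), pos


def balanced_accuracy(y_true, y_pred) -> float:
    """Macro-averaged per-class recall over the classes present in y_true."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    present = sorted(set(y_true.tolist()))
    extra = set(y_pred.tolist()) - set(present)
    if extra:
        warnings.warn(
            f"predicted class(es) absent from y_true excluded: {sorted(extra)}",
            stacklevel=2,
        )
    recalls = [
        float((y_pred[y_true == c] == c).mean()) for c in present
    ]
    return float(np.mean(recalls))


def f1_score(y_true, y_pred, averaging: str = "macro",
             positive: str | None = None) -> float:
    """Harmonic mean of precision and recall (binary) or macro mean."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if averaging == "binary":
        classes = sorted(set(y_true.tolist()))
        if positive is None:
            if len(classes) != 2:
                raise ValueError("binary F1 needs a designated positive class")
            positive = classes[-1]
        return float(
            _skm.f1_score(y_true == positive, y_pred == positive, zero_division=0)
        )
    if averaging == "macro":
        labels = sorted(set(y_true.tolist()))
        return float(
            _skm.f1_score(y_true, y_pred, labels=labels, average="macro",
                          zero_division=0)
        )
    raise ValueError(f"unknown averaging {averaging!r}")


def _binary_auc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    # rank-based AUC; ties contribute 1/2 (Mann–Whitney convention)
    return float(_skm.roc_auc_score(y_bin, scores))


def auc_ovr(y_true, scores, classes: list[str] | None = None,
            positive: str | None = None) -> float:
    """Binary or one-vs-rest macro AUC.

    ``scores`` is a 1-D positive-class score vector (binary; ``positive``
    names the scored class, defaulting to the lexicographically last label)
    or an (n, K) matrix of per-class scores with column order ``classes``.
    """
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    present = sorted(set(y_true.tolist()))
    if len(present) < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    if scores.ndim == 1:
        if len(present) != 2:
            raise ValueError("1-D scores require binary y_true")
        pos = positive if positive is not None else present[-1]
        if pos not in present:
            raise ValueError(f"positive class {pos!r} absent from y_true")
        return _binary_auc(y_true == pos, scores)
    if classes is None:
        raise ValueError("per-class score matrix requires the class order")
    aucs = []
    for c in present:
        j = classes.index(c)
        aucs.append(_binary_auc(y_true == c, scores[:, j]))
    return float(np.mean(aucs))


# --------------------------------------------------------------------------
# fold plans


@dataclass(frozen=True)
class FoldPlan:
    """k folds over node ids, stratified by node class."""

    k: int
    seed: int
    folds: tuple[tuple[frozenset[str], frozenset[str]], ...]

    def __post_init__(self) -> None:
        all_nodes = set()
        for train, val in self.folds:
            if train & val:
                raise ValueError("a node appears in both train and validation")
            all_nodes |= val
        counts = sum(len(v) for _, v in self.folds)
        if counts != len(all_nodes):
            raise ValueError("every node must validate exactly once")


def make_fold_plan(cohort: Cohort, k: int = 5, seed: int = 42) -> FoldPlan:
    node_label = cohort.node_label_map()
    nodes = np.array(sorted(node_label), dtype=object)
    y = np.array([node_label[n] for n in nodes], dtype=object)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(nodes, y):
        folds.append((frozenset(nodes[tr].tolist()), frozenset(nodes[va].tolist())))
    return FoldPlan(k, seed, tuple(folds))


@dataclass
class MetricSummary:
    """Mean ± SD across folds for BACC, AUC, F1, plus the per-fold values."""

    task: str
    n_features: int
    per_fold: dict[str, list[float]]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    skipped_folds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m, vals in self.per_fold.items():
            if vals:
                self.mean[m] = float(np.mean(vals))
                self.sd[m] = float(np.std(vals))
            else:
                self.mean[m] = float("nan")
                self.sd[m] = float("nan")


def cross_validate(
    cohort: Cohort,
    feature_names: list[str],
    spec: ClassifierSpec,
    plan: FoldPlan | None = None,
    task: str = "three_class",
) -> MetricSummary:
    """Leakage-safe cross-validated metrics for one feature subset + classifier.

    Per fold: the standardizer is fitted on the fold's training observations
    only, the classifier fitted on the standardized subset, and BACC / AUC /
    F1 computed on the validation observations.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    plan = plan or make_fold_plan(cohort)
    sub = cohort.select_features(feature_names)
    y_all, positive = task_labels(sub.labels, task)
    node_ids = sub.node_ids
    per_fold: dict[str, list[float]] = {"bacc": [], "auc": [], "f1": []}
    skipped: list[str] = []
    for fold_idx, (train_nodes, val_nodes) in enumerate(plan.folds):
        tr_mask = np.array([n in train_nodes for n in node_ids])
        va_mask = np.array([n in val_nodes for n in node_ids])
        y_tr, y_va = y_all[tr_mask], y_all[va_mask]
        if len(set(y_tr.tolist())) < 2 or len(set(y_va.tolist())) < 2:
            skipped.append(f"fold {fold_idx}: a class is absent")
            continue
        train_c = sub.select_rows(tr_mask)
        val_c = sub.select_rows(va_mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_s, (val_s,), _ = fit_apply_standardizer(train_c, [val_c])
        model = fit(spec, train_s.X, y_tr)
        proba = model.predict_proba(val_s.X)
        pred = model.predict(val_s.X)
        per_fold["bacc"].append(balanced_accuracy(y_va, pred))
        if positive is not None:
            pos_col = model.classes.index(positive)
            per_fold["auc"].append(
                auc_ovr(y_va, proba[:, pos_col], positive=positive)
            )
            per_fold["f1"].append(
                f1_score(y_va, pred, averaging="binary", positive=positive)
            )
        else:
            per_fold["auc"].append(auc_ovr(y_va, proba, classes=model.classes))
            per_fold["f1"].append(f1_score(y_va, pred, averaging="macro"))
    return MetricSummary(task, len(feature_names), per_fold, skipped_folds=skipped)
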