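"""Class-specific one-vs-rest ensemble with probability calibration.

Per class, a submodel is fitted on that class's best grid configuration (its
feature subset and classifier) against a binary class-vs-rest relabeling; the
raw positive-class scores are calibrated with a Platt-style sigmoid fitted on
out-of-fold scores from an internal node-grouped 3-fold split.  The ensemble
predicts by confidence voting: argmax of calibrated per-class probabilities,
exact ties broken by clinical severity (ecs > pathologic > reactive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .classifiers import ClassifierSpec, FittedModel, fit
from .cohort import Cohort, LABELS
from .evaluation import (
    auc_ovr,
    balanced_accuracy,
    f1_score,
)
from .preprocessing import Standardizer, fit_standardizer
from .selection.base import _grouped_folds

#: tie-break priority, most severe first
SEVERITY_ORDER = ("ecs", "pathologic", "reactive")


@dataclass
class ClassSubmodel:
    target: str
    features: list[str]
    spec: ClassifierSpec
    standardizer: Standardizer
    model: FittedModel
    calibrator: LogisticRegression | None

    def raw_score(self, cohort: Cohort) -> np.ndarray:
        sub = self.standardizer.transform(cohort.select_features(self.features))
        proba = self.model.predict_proba(sub.X)
        return proba[:, self.model.classes.index(self.target)]

    def confidence(self, cohort: Cohort) -> np.ndarray:
        s = self.raw_score(cohort)
        if self.calibrator is None:
            return s
        return self.calibrator.predict_proba(s.reshape(-1, 1))[:, 1]


@dataclass
class OvREnsemble:
    submodels: dict[str, ClassSubmodel]
    severity: tuple[str, ...] = SEVERITY_ORDER

    def __post_init__(self) -> None:
        if set(self.submodels) != set(LABELS):
            raise ValueError(f"need exactly one submodel per class {LABELS}")

    def required_features(self) -> list[str]:
        seen: list[str] = []
        for sm in self.submodels.values():
            for f in sm.features:
                if f not in seen:
                    seen.append(f)
        return seen

    def confidences(self, cohort: Cohort) -> tuple[np.ndarray, list[str]]:
        """Renormalized per-class confidence rows (columns in LABELS order)."""
        missing = [f for f in self.required_features()
                   if f not in cohort.manifest.family]
        if missing:
            raise KeyError(f"cohort is missing feature(s): {missing[:5]}")
        raw = np.column_stack(
            [self.submodels[c].confidence(cohort) for c in LABELS]
        )
        s = raw.sum(axis=1, keepdims=True)
        return raw / np.where(s > 0, s, 1.0), list(LABELS)

    def predict(self, cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
        """(labels, renormalized confidence rows) for every observation."""
        conf, classes = self.confidences(cohort)
        sev_rank = {c: i for i, c in enumerate(self.severity)}
        labels = []
        for row in conf:
            best = row.max()
            tied = [classes[j] for j in np.flatnonzero(row == best)]
            labels.append(min(tied, key=lambda c: sev_rank[c]))
        return np.array(labels, dtype=object), conf


def _fit_calibrator(scores: np.ndarray, y_bin: np.ndarray) -> LogisticRegression | None:
    if len(set(y_bin.tolist())) < 2:
        return None
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(scores.reshape(-1, 1), y_bin)
    return lr


def fit_ensemble(
    cohort_train: Cohort,
    per_class: dict[str, tuple[list[str], ClassifierSpec]],
    seed: int = 0,
    calibration_folds: int = 3,
) -> OvREnsemble:
    """Fit the three class-specific submodels on the training cohort.

    ``per_class`` maps each class label to its (feature subset, classifier
    spec) — typically the best Pareto configuration of that class's
    one-vs-rest task.
    """
    labels = cohort_train.labels
    submodels: dict[str, ClassSubmodel] = {}
    for i, cls in enumerate(LABELS):
        if cls not in per_class:
            raise ValueError(f"no configuration provided for class {cls!r}")
        if not (labels == cls).any():
            raise ValueError(f"class {cls!r} absent from the training cohort")
        features, spec = per_class[cls]
        if not features:
            raise ValueError(f"empty feature subset for class {cls!r}")
        sub = cohort_train.select_features(features)
        y_bin = np.where(labels == cls, cls, "rest").astype(object)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = fit_standardizer(sub)
            sub_s = std.transform(sub)
        spec_seeded = spec.with_seed(seed + i)
        # out-of-fold scores for the sigmoid calibrator
        folds = _grouped_folds(sub.node_ids, y_bin, calibration_folds,
                               seed + 1000 + i)
        oof = np.full(sub.n, np.nan)
        for tr, va in folds:
            if len(set(y_bin[tr].tolist())) < 2:
                continue
            m = fit(spec_seeded, sub_s.X[tr], y_bin[tr])
            oof[va] = m.predict_proba(sub_s.X[va])[:, m.classes.index(cls)]
        have = ~np.isnan(oof)
        calibrator = (
            _fit_calibrator(oof[have], (y_bin[have] == cls).astype(int))
            if have.any() else None
        )
        model = fit(spec_seeded, sub_s.X, y_bin)
        submodels[cls] = ClassSubmodel(cls, list(features), spec_seeded, std,
                                       model, calibrator)
    return OvREnsemble(submodels)


@dataclass
class EnsembleEvaluation:
    """Held-out evaluation: per-class metrics, their range/mean/SD across
    classes, and the 3x3 confusion matrix (rows true, columns predicted)."""

    per_class: dict[str, dict[str, float]]
    summary: dict[str, dict[str, float]]  # metric -> {min, max, mean, sd}
    confusion: np.ndarray
    classes: tuple[str, ...]
    macro_bacc: float
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


def evaluate_ensemble(ensemble: OvREnsemble, cohort_test: Cohort) -> EnsembleEvaluation:
    """Per-class one-vs-rest metrics, across-class summary, confusion counts."""
    from sklearn.metrics import roc_curve

    y_true = cohort_test.labels
    pred, conf = ensemble.predict(cohort_test)
    classes = tuple(LABELS)
    confusion = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, pred):
        confusion[classes.index(t), classes.index(p)] += 1

    per_class: dict[str, dict[str, float]] = {}
    roc_curves = {}
    for j, cls in enumerate(classes):
        if not (y_true == cls).any():
            per_class[cls] = {m: float("nan") for m in ("bacc", "auc", "f1")}
            continue
        t_bin = np.where(y_true == cls, cls, "rest").astype(object)
        p_bin = np.where(pred == cls, cls, "rest").astype(object)
        scores = conf[:, j]
        per_class[cls] = {
            "bacc": balanced_accuracy(t_bin, p_bin),
            "auc": auc_ovr(t_bin, scores, positive=cls),
            "f1": f1_score(t_bin, p_bin, averaging="binary", positive=cls),
        }
        fpr, tpr, _ = roc_curve((y_true == cls).astype(int), scores)
        roc_curves[cls] = (fpr, tpr)

    summary = {}
    for m in ("bacc", "auc", "f1"):
        vals = [per_class[c][m] for c in classes
                if np.isfinite(per_class[c][m])]
        summary[m] = {
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals)),
        }
    macro_bacc = balanced_accuracy(y_true, pred)
    return EnsembleEvaluation(per_class, summary, confusion, classes,
                              macro_bacc, roc_curves)
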