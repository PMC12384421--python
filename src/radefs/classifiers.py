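"""Uniform adapter over the six classifier configurations.

The six kinds — LDA, SVM with linear / sigmoid / RBF kernels, random forest,
and XGBoost — are library-backed (scikit-learn, xgboost) with the reference
hyperparameters as defaults: RF 200 trees at max depth 42, XGBoost learning
rate 0.01.  The SVM kernel formulas are additionally implemented natively in
:func:`kernel_value` so their algebra is testable in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

KINDS = ("lda", "svm_linear", "svm_sigmoid", "svm_rbf", "rf", "xgb")

#: reference defaults; anything unspecified upstream is pinned here for
#: reproducibility
DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "lda": {},
    "svm_linear": {"C": 1.0},
    "svm_sigmoid": {"C": 1.0, "alpha": "auto", "c": 0.0},  # alpha 'auto' = 1/d
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "rf": {"n_estimators": 200, "max_depth": 42},
    "xgb": {"learning_rate": 0.01, "n_estimators": 200, "max_depth": 6,
            "subsample": 1.0, "reg_lambda": 1.0, "reg_alpha": 0.0},
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        hp = {**DEFAULT_HYPERPARAMS[self.kind], **self.hyperparams}
        if self.kind == "svm_rbf" and isinstance(hp["gamma"], (int, float)):
            if hp["gamma"] <= 0:
                raise ValueError("RBF gamma must be positive")
        if self.kind in ("rf", "xgb") and hp.get("n_estimators", 1) < 1:
            raise ValueError("tree count must be >= 1")

    def resolved(self) -> dict[str, Any]:
        return {**DEFAULT_HYPERPARAMS[self.kind], **self.hyperparams}

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=seed)


def kernel_value(spec: ClassifierSpec, xi, xj) -> float:
    """The SVM kernel K(xi, xj): dot product (linear), tanh(alpha xi.xj + c)
    (sigmoid), or exp(-gamma ||xi - xj||^2) (RBF)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    hp = spec.resolved()
    if spec.kind == "svm_linear":
        return float(xi @ xj)
    if spec.kind == "svm_sigmoid":
        alpha = hp["alpha"]
        if alpha == "auto":
            alpha = 1.0 / len(xi)
        return float(np.tanh(alpha * (xi @ xj) + hp["c"]))
    if spec.kind == "svm_rbf":
        gamma = hp["gamma"]
        if not isinstance(gamma, (int, float)):
            raise ValueError("kernel_value needs a numeric RBF gamma")
        return float(np.exp(-gamma * ((xi - xj) ** 2).sum()))
    raise ValueError(f"{spec.kind!r} is not an SVM kernel")


def make_estimator(spec: ClassifierSpec, n_features: int | None = None,
                   n_samples: int | None = None):
    """Instantiate the scikit-learn / xgboost estimator behind a spec."""
    hp = spec.resolved()
    if spec.kind == "lda":
        # shrinkage keeps the pooled covariance invertible when d >= n in a fold
        if n_features is not None and n_samples is not None and n_features >= n_samples:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis(**hp)
    if spec.kind == "svm_linear":
        return SVC(kernel="linear", C=hp["C"], probability=True,
                   random_state=spec.seed)
    if spec.kind == "svm_sigmoid":
        gamma = "auto" if hp["alpha"] == "auto" else hp["alpha"]
        return SVC(kernel="sigmoid", C=hp["C"], gamma=gamma, coef0=hp["c"],
                   probability=True, random_state=spec.seed)
    if spec.kind == "svm_rbf":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], probability=True,
                   random_state=spec.seed)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=spec.seed, n_jobs=1,
        )
    if spec.kind == "xgb":
        return XGBClassifier(
            learning_rate=hp["learning_rate"], n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"], subsample=hp["subsample"],
            reg_lambda=hp["reg_lambda"], reg_alpha=hp["reg_alpha"],
            random_state=spec.seed, n_jobs=1, verbosity=0,
            eval_metric="logloss",
        )
    raise AssertionError(spec.kind)


@dataclass
class FittedModel:
    """A fitted classifier plus the class labels it can predict."""

    spec: ClassifierSpec
    classes: list[str]
    estimator: Any

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = self.estimator.predict_proba(X)
        s = proba.sum(axis=1, keepdims=True)
        return proba / np.where(s > 0, s, 1.0)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        return np.array([self.classes[i] for i in idx], dtype=object)


def fit(spec: ClassifierSpec, X_train, y_train) -> FittedModel:
    """Fit a classifier; labels may be arbitrary strings."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    classes = sorted(set(y_train.tolist()))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    y_codes = np.array([classes.index(y) for y in y_train])
    est = make_estimator(spec, n_features=X_train.shape[1],
                         n_samples=X_train.shape[0])
    with warnings.catch_warnings():
        # SVC(probability=True) is the adapter's documented probability mode
        warnings.filterwarnings("ignore", category=FutureWarning)
        est.fit(X_train, y_codes)
    return FittedModel(spec, classes, est)
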