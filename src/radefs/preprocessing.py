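"""Z-score standardization, normality filtering, and leakage-safe splitting.

All three operations respect the repeated-measure structure of the cohort:
standardization parameters are estimated on training observations only, and
splits operate on nodes (stratified by node class) so that the three phase
observations of a node never straddle a train/test boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort, LABELS


@dataclass
class Standardizer:
    """Per-feature Z-score parameters (sample SD, ddof=1), fitted on train.

    Constant features (sigma == 0) are flagged and dropped from every cohort
    the standardizer is applied to.
    """

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str]
    fitted_on: frozenset[str]

    def transform(self, cohort: Cohort) -> Cohort:
        # any cohort containing the retained features is accepted
        kept = cohort.select_features(self.feature_names)
        X = (kept.X - self.mean) / self.sd
        return Cohort(X, kept.manifest, list(kept.meta))


def fit_standardizer(train: Cohort) -> Standardizer:
    if train.n == 0:
        raise ValueError("cannot fit a standardizer on an empty cohort")
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=1) if train.n > 1 else np.zeros(train.d)
    keep = sd > 0
    dropped = [n for n, k in zip(train.manifest.names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant feature(s): {dropped[:5]}",
            stacklevel=2,
        )
    names = [n for n, k in zip(train.manifest.names, keep) if k]
    return Standardizer(
        feature_names=names,
        mean=mean[keep],
        sd=sd[keep],
        dropped=dropped,
        fitted_on=frozenset(m.observation_id for m in train.meta),
    )


def fit_apply_standardizer(
    train: Cohort, others: list[Cohort] | None = None
) -> tuple[Cohort, list[Cohort], Standardizer]:
    """Fit on ``train`` only; apply to train and every cohort in ``others``."""
    std = fit_standardizer(train)
    return std.transform(train), [std.transform(c) for c in (others or [])], std


@dataclass
class NDFReport:
    """Shapiro–Wilk normality screen: W statistic and p per feature.

    ``ndf_names`` lists the features retained as normally distributed
    (p > alpha); constant features are flagged undefined and never retained.
    """

    alpha: float
    statistic: dict[str, float]
    pvalue: dict[str, float]
    undefined: list[str]
    ndf_names: list[str]


def ndf_filter(cohort: Cohort, alpha: float = 0.05) -> NDFReport:
    """Retain a feature as an NDF iff its Shapiro–Wilk p-value exceeds alpha."""
    if cohort.n < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    stat: dict[str, float] = {}
    pval: dict[str, float] = {}
    undefined: list[str] = []
    ndf: list[str] = []
    for j, name in enumerate(cohort.manifest.names):
        col = cohort.X[:, j]
        if np.ptp(col) == 0:
            undefined.append(name)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns for n > 5000
            w, p = stats.shapiro(col)
        stat[name], pval[name] = float(w), float(p)
        if p > alpha:
            ndf.append(name)
    return NDFReport(alpha, stat, pval, undefined, ndf)


class StratificationError(ValueError):
    pass


def grouped_stratified_split(
    cohort: Cohort, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """80:20-style split over nodes, stratified by node class.

    Every observation of a node lands on the same side; per class, the number
    of test nodes is round(test_fraction * class node count), at least 1.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    node_label = cohort.node_label_map()
    rng = np.random.default_rng(seed)
    test_nodes: set[str] = set()
    for cls in LABELS:
        nodes = sorted(n for n, l in node_label.items() if l == cls)
        if not nodes:
            continue
        if len(nodes) < 2:
            raise StratificationError(
                f"class {cls!r} has a single node; cannot stratify"
            )
        n_test = int(round(test_fraction * len(nodes)))
        n_test = min(max(n_test, 1), len(nodes) - 1)
        test_nodes.update(rng.permutation(nodes)[:n_test])
    is_test = np.array([m.node_id in test_nodes for m in cohort.meta])
    return cohort.select_rows(~is_test), cohort.select_rows(is_test)
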