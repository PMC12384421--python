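"""Evaluation metrics against hand-computed and brute-force oracles, and the
grouped fold-plan contracts."""

import numpy as np
import pytest

from radefs.classifiers import ClassifierSpec
from radefs.evaluation import (
    auc_ovr,
    balanced_accuracy,
    cross_validate,
    f1_score,
    make_fold_plan,
)

from conftest import make_grouped_cohort


def brute_force_auc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Concordant-pair counting over all positive-negative pairs (ties 1/2)."""
    pos = scores[y_bin]
    neg = scores[~y_bin]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestBalancedAccuracy:
    def test_perfect_binary_prediction(self):
        assert balanced_accuracy(["a", "b"], ["a", "b"]) == 1.0

    def test_majority_vote_on_imbalanced_binary(self):
        # recalls: class 0 -> 1.0, class 1 -> 0.0
        assert balanced_accuracy([0, 0, 0, 1], [0, 0, 0, 0]) == 0.5

    def test_three_class_hand_example(self):
        y = [0, 0, 1, 1, 2, 2]
        yh = [0, 1, 1, 1, 2, 0]
        assert balanced_accuracy(y, yh) == pytest.approx(2 / 3)

    def test_macro_symmetry_under_relabeling(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 60)
        yh = rng.integers(0, 3, 60)
        relabel = {0: "x", 1: "y", 2: "z"}
        a = balanced_accuracy(y, yh)
        b = balanced_accuracy([relabel[v] for v in y], [relabel[v] for v in yh])
        assert a == pytest.approx(b)

    def test_predicted_only_class_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            balanced_accuracy(["a", "a"], ["a", "b"])


class TestF1:
    def test_binary_hand_example(self):
        # precision 0.5, recall 0.5
        assert f1_score([1, 1, 0, 0], [1, 0, 1, 0], averaging="binary",
                        positive=1) == pytest.approx(0.5)

    def test_perfect_prediction(self):
        assert f1_score(["a", "b"], ["a", "b"], averaging="macro") == 1.0

    def test_all_wrong_balanced_binary_is_zero(self):
        assert f1_score([0, 1, 0, 1], [1, 0, 1, 0], averaging="binary",
                        positive=1) == 0.0

    def test_zero_denominator_is_zero_not_error(self):
        assert f1_score([0, 0, 1], [0, 0, 0], averaging="binary",
                        positive=1) == 0.0


class TestAUC:
    def test_perfect_ranking(self):
        assert auc_ovr([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_partial_ranking_hand_example(self):
        assert auc_ovr([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == pytest.approx(0.75)

    def test_constant_scores_give_half(self):
        assert auc_ovr([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            auc_ovr([1, 1], [0.2, 0.3])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 51)
            y = rng.integers(0, 2, n).astype(bool)
            if y.all() or not y.any():
                continue
            # discrete scores force ties
            scores = rng.integers(0, 6, n).astype(float)
            assert auc_ovr(y.astype(int), scores, positive=1) == pytest.approx(
                brute_force_auc(y, scores)
            )

    def test_multiclass_is_mean_of_ovr_aucs(self):
        rng = np.random.default_rng(1)
        y = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
        S = rng.random((30, 3))
        classes = ["a", "b", "c"]
        expected = np.mean([
            auc_ovr((y == c).astype(int), S[:, j], positive=1)
            for j, c in enumerate(classes)
        ])
        assert auc_ovr(y, S, classes=classes) == pytest.approx(expected)


class TestFoldPlan:
    def _cohort(self, seed=0):
        def label_of(i):
            return ("reactive", "pathologic", "ecs")[i % 3]

        return make_grouped_cohort(30, 3, 4, label_of,
                                   lambda rng, n, d: rng.standard_normal((n, d)),
                                   seed=seed)

    def test_folds_partition_nodes_each_validates_once(self):
        cohort = self._cohort()
        plan = make_fold_plan(cohort, k=5, seed=42)
        all_nodes = set(m.node_id for m in cohort.meta)
        validated = [n for _, va in plan.folds for n in va]
        assert len(validated) == len(all_nodes)
        assert set(validated) == all_nodes
        for tr, va in plan.folds:
            assert not tr & va

    def test_stratification_within_one_node_of_ideal(self):
        cohort = self._cohort()
        plan = make_fold_plan(cohort, k=5, seed=42)
        node_label = cohort.node_label_map()
        for _, va in plan.folds:
            for cls in ("reactive", "pathologic", "ecs"):
                n_cls = sum(node_label[n] == cls for n in va)
                assert abs(n_cls - 2) <= 1  # 10 nodes/class over 5 folds

    def test_plan_deterministic_in_seed(self):
        cohort = self._cohort()
        assert make_fold_plan(cohort, 5, 42) == make_fold_plan(cohort, 5, 42)


class TestCrossValidate:
    def test_separable_cohort_scores_perfectly_with_zero_sd(self):
        def label_of(i):
            return ("reactive", "pathologic", "ecs")[i % 3]

        def X_fn(rng, n, d):
            X = rng.standard_normal((n, d)) * 0.05
            X[:, 0] += np.repeat([(i % 3) * 10.0 for i in range(n // 3)], 3)
            return X

        cohort = make_grouped_cohort(30, 3, 3, label_of, X_fn)
        summary = cross_validate(cohort, list(cohort.manifest.names),
                                 ClassifierSpec("lda"), task="three_class")
        assert summary.mean["bacc"] == 1.0
        assert summary.sd["bacc"] == 0.0
        assert summary.n_features == 3

    def test_mean_is_arithmetic_mean_of_fold_values(self):
        from radefs.evaluation import MetricSummary

        s = MetricSummary("three_class", 4,
                          {"bacc": [0.8, 0.9, 1.0, 0.7, 0.6],
                           "auc": [1.0], "f1": [1.0]})
        assert s.mean["bacc"] == pytest.approx(0.8)

    def test_binary_task_relabels_and_uses_positive_class(self):
        def label_of(i):
            return ("reactive", "pathologic", "ecs")[i % 3]

        def X_fn(rng, n, d):
            X = rng.standard_normal((n, d)) * 0.05
            X[:, 0] += np.repeat([10.0 if i % 3 == 2 else 0.0
                                  for i in range(n // 3)], 3)
            return X

        cohort = make_grouped_cohort(30, 3, 2, label_of, X_fn)
        summary = cross_validate(cohort, list(cohort.manifest.names),
                                 ClassifierSpec("lda"), task="ecs_vs_rest")
        assert summary.mean["bacc"] == 1.0
        assert summary.mean["auc"] == 1.0
        assert summary.mean["f1"] == 1.0
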