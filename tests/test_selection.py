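"""Wrapper selection strategies: consensus, GA fitness, RFE, importance."""

import itertools

import numpy as np
import pytest

from radefs.classifiers import ClassifierSpec
from radefs.selection import (
    GAParams,
    SelectionRequest,
    SubsetScorer,
    aggregate_runs,
    ga_select,
    importance_select,
    rfe_select,
)
from radefs.selection.ga import FitnessSpec, fitness_value
from radefs.selection.wrappers import CapabilityError
from radefs.simulate import generate_cohort, recovery_config

from conftest import make_cohort, make_grouped_cohort


class TestAggregateRuns:
    def test_hand_counted_frequencies(self):
        selected, freq = aggregate_runs([{"a", "b"}, {"a", "b"}, {"a", "c"}], 2)
        assert selected == ["a", "b"]
        assert freq == {"a": 1.0, "b": pytest.approx(2 / 3),
                        "c": pytest.approx(1 / 3)}

    def test_single_run_truncated_deterministically(self):
        selected, _ = aggregate_runs([["d", "b", "c"]], 2)
        assert selected == ["b", "c"]  # lexicographic tie-break at freq 1

    def test_identical_runs_return_common_subset(self):
        selected, freq = aggregate_runs([{"x", "y"}] * 5, 2)
        assert set(selected) == {"x", "y"}
        assert all(v == 1.0 for v in freq.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([], 2)


class TestFitness:
    def test_equal_accuracy_favors_smaller_subset(self):
        f5 = fitness_value(0.9, 5, 40, FitnessSpec())
        f10 = fitness_value(0.9, 10, 40, FitnessSpec())
        assert f5 > f10

    def test_zero_size_weight_ignores_feature_count(self):
        spec = FitnessSpec(lambda1=0.0)
        assert fitness_value(0.9, 5, 40, spec) == fitness_value(0.9, 35, 40, spec)

    def test_soft_constraint_penalizes_deviation_from_target(self):
        spec = FitnessSpec(lambda1=0.0, p_target=5, kappa=0.1)
        at = fitness_value(0.9, 5, 40, spec)
        off = fitness_value(0.9, 8, 40, spec)
        assert at - off == pytest.approx(0.3)

    def test_superset_never_worse_when_only_accuracy_counts(self):
        # monotone: adding features cannot reduce attainable CV BACC by much;
        # check the exact weight-zero algebra instead of the stochastic claim
        spec = FitnessSpec(lambda1=0.0)
        assert fitness_value(0.95, 30, 40, spec) > fitness_value(0.90, 5, 40, spec)


def _planted_cohort(seed=0, n_nodes=60, d=12, n_signal=3, effect=4.0):
    """Three-class cohort where the first n_signal features carry the signal."""
    def label_of(i):
        return ("reactive", "pathologic", "ecs")[i % 3]

    def X_fn(rng, n, dd):
        X = rng.standard_normal((n, dd))
        shift = np.repeat([(i % 3) - 1.0 for i in range(n // 3)], 3)
        for j in range(n_signal):
            X[:, j] += effect * shift
        return X

    return make_grouped_cohort(n_nodes, 3, d, label_of, X_fn, seed=seed)


class TestGA:
    def test_recovers_dominant_features_with_small_budget(self):
        cohort = _planted_cohort(seed=1)
        res = ga_select(
            cohort,
            SelectionRequest("ga", p=3, runs=3, seed=0),
            params=GAParams(population=60, generations=20),
        )
        assert set(res.selected) == {"firstorder_F0", "firstorder_F1",
                                     "firstorder_F2"}

    def test_best_fitness_trace_nondecreasing_with_elitism(self):
        cohort = _planted_cohort(seed=2)
        res = ga_select(
            cohort,
            SelectionRequest("ga", p=3, runs=2, seed=1),
            params=GAParams(population=40, generations=15, elitism=1),
        )
        for t in res.trace:
            trace = t["best_fitness"]
            assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_matches_exhaustive_subset_search(self):
        # brute-force oracle: best CV BACC over all C(10,3) subsets
        cohort = _planted_cohort(seed=3, d=10, effect=2.0)
        pool = list(cohort.manifest.names)
        scorer = SubsetScorer(cohort, pool, seed=0)
        fs = FitnessSpec()
        best_oracle = -np.inf
        for combo in itertools.combinations(range(10), 3):
            mask = np.zeros(10, dtype=bool)
            mask[list(combo)] = True
            best_oracle = max(
                best_oracle,
                fitness_value(scorer.score_mask(mask), 3, 10, fs),
            )
        hits = 0
        for seed in range(10):
            res = ga_select(
                cohort,
                SelectionRequest("ga", p=3, runs=1, seed=seed),
                fitness=FitnessSpec(p_target=3, kappa=0.5),
                params=GAParams(population=150, generations=40),
            )
            got = fitness_value(scorer.score_names(res.selected), 3, 10, fs)
            hits += got >= best_oracle - 1e-9
        assert hits >= 8

    def test_result_size_and_pool_containment(self):
        cohort = _planted_cohort(seed=4)
        res = ga_select(cohort, SelectionRequest("ga", p=4, runs=2, seed=0),
                        params=GAParams(population=30, generations=10))
        assert len(res.selected) == 4
        assert set(res.selected) <= set(cohort.manifest.names)


class TestRFE:
    def test_exact_linear_signal_selects_the_signal_feature(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = ["reactive" if x > 0 else "pathologic" for x in X[:, 0]]
        cohort = make_cohort(X, y)
        res = rfe_select(
            cohort,
            SelectionRequest("rfe", p=2, estimator=ClassifierSpec("svm_linear"),
                             runs=1, seed=0),
        )
        assert "firstorder_F0" in res.selected

    def test_identity_selection_when_p_equals_d(self):
        cohort = _planted_cohort(seed=5, d=6)
        res = rfe_select(
            cohort,
            SelectionRequest("rfe", p=6, estimator=ClassifierSpec("lda"),
                             runs=1, seed=0),
        )
        assert set(res.selected) == set(cohort.manifest.names)

    def test_elimination_schedule_round_count(self, monkeypatch):
        import radefs.selection.wrappers as W

        fits = []
        orig = W.make_estimator

        def counting(spec, **kw):
            est = orig(spec, **kw)
            orig_fit = est.fit

            def fit_logged(X, y):
                fits.append(X.shape[1])
                return orig_fit(X, y)

            est.fit = fit_logged
            return est

        monkeypatch.setattr(W, "make_estimator", counting)
        cohort = _planted_cohort(seed=6, d=4)
        rfe_select(cohort, SelectionRequest(
            "rfe", p=2, estimator=ClassifierSpec("lda"), runs=1, seed=0))
        assert fits == [4, 3]  # two rounds at step 1

    def test_kernel_svm_estimator_is_capability_error(self):
        cohort = _planted_cohort(seed=7)
        with pytest.raises(CapabilityError):
            rfe_select(cohort, SelectionRequest(
                "rfe", p=2, estimator=ClassifierSpec("svm_rbf"), runs=1, seed=0))

    def test_deterministic_estimator_is_pure_function(self):
        cohort = _planted_cohort(seed=8)
        req = SelectionRequest("rfe", p=3, estimator=ClassifierSpec("lda"),
                               runs=1, seed=0)
        assert rfe_select(cohort, req).selected == rfe_select(cohort, req).selected


class TestImportance:
    def test_dominant_feature_always_selected(self):
        cohort = _planted_cohort(seed=9, n_signal=1, effect=4.0)
        res = importance_select(
            cohort,
            SelectionRequest("rf_importance", p=2, runs=10, seed=0,
                             estimator=ClassifierSpec("rf", {"n_estimators": 30})),
        )
        assert res.frequency["firstorder_F0"] == 1.0
        assert "firstorder_F0" in res.selected

    def test_same_seed_reproduces_result(self):
        cohort = _planted_cohort(seed=10)
        req = SelectionRequest("rf_importance", p=3, runs=2, seed=5,
                               estimator=ClassifierSpec("rf", {"n_estimators": 20}))
        a = importance_select(cohort, req)
        b = importance_select(cohort, req)
        assert a.selected == b.selected and a.frequency == b.frequency

    def test_pure_noise_has_no_stable_winner(self):
        def label_of(i):
            return ("reactive", "pathologic", "ecs")[i % 3]

        cohort = make_grouped_cohort(
            40, 3, 20, label_of,
            lambda rng, n, d: rng.standard_normal((n, d)), seed=11,
        )
        res = importance_select(
            cohort,
            SelectionRequest("rf_importance", p=3, runs=50, seed=0,
                             estimator=ClassifierSpec("rf", {"n_estimators": 20})),
        )
        assert max(res.frequency.values()) < 0.5

    def test_xgb_variant_runs(self):
        cohort = _planted_cohort(seed=12, n_signal=1)
        res = importance_select(
            cohort,
            SelectionRequest("xgb_importance", p=2, runs=3, seed=0,
                             estimator=ClassifierSpec("xgb", {"n_estimators": 20})),
        )
        assert "firstorder_F0" in res.selected


class TestRequestValidation:
    def test_p_larger_than_pool_rejected(self):
        cohort = _planted_cohort(seed=13, d=4)
        with pytest.raises(ValueError, match="exceeds"):
            rfe_select(cohort, SelectionRequest(
                "rfe", p=5, estimator=ClassifierSpec("lda"), runs=1, seed=0))

    def test_bad_method_and_runs_rejected(self):
        with pytest.raises(ValueError):
            SelectionRequest("pca", p=3)
        with pytest.raises(ValueError):
            SelectionRequest("ga", p=3, runs=0)

    def test_ndf_only_restricts_pool(self):
        rng = np.random.default_rng(14)
        normal = rng.standard_normal((90, 2))
        lognormal = np.exp(rng.standard_normal((90, 2)) * 1.5)
        X = np.column_stack([normal, lognormal])
        y = ["reactive" if i < 45 else "pathologic" for i in range(90)]
        cohort = make_cohort(X, y)
        res = rfe_select(cohort, SelectionRequest(
            "rfe", p=2, estimator=ClassifierSpec("lda"), ndf_only=True,
            runs=1, seed=0))
        assert set(res.selected) == {"firstorder_F0", "firstorder_F1"}


class TestPlantedRecovery:
    """Each strategy recovers planted signal on the dedicated fixture."""

    @pytest.fixture(scope="class")
    def fixture_cohort(self):
        return generate_cohort(recovery_config(seed=17))

    def test_rfe_linear_recovers_planted(self, fixture_cohort):
        cohort, truth = fixture_cohort
        res = rfe_select(cohort, SelectionRequest(
            "rfe", p=5, estimator=ClassifierSpec("svm_linear"), runs=1, seed=0))
        assert len(set(res.selected) & truth.informative()) >= 4

    def test_rf_importance_recovers_planted(self, fixture_cohort):
        cohort, truth = fixture_cohort
        res = importance_select(cohort, SelectionRequest(
            "rf_importance", p=5, runs=10, seed=0))
        assert len(set(res.selected) & truth.informative()) >= 4

    def test_ga_recovers_planted(self, fixture_cohort):
        cohort, truth = fixture_cohort
        res = ga_select(cohort, SelectionRequest("ga", p=5, runs=5, seed=0),
                        params=GAParams(population=100, generations=30))
        assert len(set(res.selected) & truth.informative()) >= 4
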