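"""Standardization, normality screening, grouped splitting."""

import numpy as np
import pytest

from radefs.preprocessing import (
    StratificationError,
    fit_apply_standardizer,
    grouped_stratified_split,
    ndf_filter,
)

from conftest import make_cohort, make_grouped_cohort


class TestStandardizer:
    def test_symmetric_three_point_column(self):
        train = make_cohort(np.array([[1.0], [2.0], [3.0]]),
                            ["reactive", "pathologic", "ecs"])
        train_s, _, std = fit_apply_standardizer(train)
        np.testing.assert_allclose(train_s.X[:, 0], [-1.0, 0.0, 1.0])

    def test_transformed_train_has_zero_mean_unit_sample_sd(self):
        rng = np.random.default_rng(0)
        train = make_cohort(rng.standard_normal((40, 6)) * 5 + 3,
                            ["reactive"] * 20 + ["pathologic"] * 20)
        train_s, _, _ = fit_apply_standardizer(train)
        np.testing.assert_allclose(train_s.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(train_s.X.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_test_column_at_train_mean_maps_to_zero(self):
        train = make_cohort(np.array([[1.0], [2.0], [3.0]]),
                            ["reactive", "pathologic", "ecs"])
        test = make_cohort(np.array([[2.0], [2.0]]), ["reactive", "ecs"],
                           node_ids=["T1", "T2"])
        _, (test_s,), _ = fit_apply_standardizer(train, [test])
        np.testing.assert_allclose(test_s.X, 0.0)

    def test_constant_column_dropped_everywhere(self):
        train = make_cohort(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]),
                            ["reactive", "pathologic", "ecs"])
        with pytest.warns(UserWarning, match="constant"):
            train_s, _, std = fit_apply_standardizer(train)
        assert train_s.d == 1
        assert std.dropped == ["firstorder_F0"]

    def test_parameters_depend_only_on_training_rows(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        train = make_cohort(X, ["reactive"] * 10 + ["pathologic"] * 10)
        test_plain = make_cohort(rng.standard_normal((5, 3)),
                                 ["ecs"] * 5, node_ids=[f"T{i}" for i in range(5)])
        outlier = test_plain.X.copy()
        outlier[0] = 1e6  # planted test-only outlier
        test_out = make_cohort(outlier, ["ecs"] * 5,
                               node_ids=[f"T{i}" for i in range(5)])
        _, _, std_a = fit_apply_standardizer(train, [test_plain])
        _, _, std_b = fit_apply_standardizer(train, [test_out])
        np.testing.assert_array_equal(std_a.mean, std_b.mean)
        np.testing.assert_array_equal(std_a.sd, std_b.sd)


class TestNDFFilter:
    def _cohort(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        normal = rng.standard_normal(n)
        lognormal = np.exp(rng.standard_normal(n))
        constant = np.full(n, 2.0)
        labels = (["reactive"] * (n // 2) + ["pathologic"] * (n - n // 2))
        return make_cohort(np.column_stack([normal, lognormal, constant]), labels)

    def test_normal_kept_lognormal_rejected_constant_undefined(self):
        report = ndf_filter(self._cohort(), alpha=0.05)
        assert "firstorder_F0" in report.ndf_names
        assert "firstorder_F1" not in report.ndf_names
        assert report.undefined == ["firstorder_F2"]

    def test_statistic_matches_reference_routine(self):
        from scipy import stats

        cohort = self._cohort(seed=3)
        report = ndf_filter(cohort, alpha=0.05)
        w, p = stats.shapiro(cohort.X[:, 0])
        assert report.statistic["firstorder_F0"] == pytest.approx(w)
        assert report.pvalue["firstorder_F0"] == pytest.approx(p)

    def test_alpha_boundaries(self):
        cohort = self._cohort()
        assert ndf_filter(cohort, alpha=1.0).ndf_names == []
        report = ndf_filter(cohort, alpha=0.0)
        # alpha=0 keeps every non-constant feature (p > 0 always)
        assert set(report.ndf_names) == {"firstorder_F0", "firstorder_F1"}


class TestGroupedSplit:
    def _cohort(self, nodes_per_class=10, seed=0):
        def label_of(i):
            return ("reactive", "pathologic", "ecs")[i % 3]

        return make_grouped_cohort(
            nodes_per_class * 3, 3, 4, label_of,
            lambda rng, n, d: rng.standard_normal((n, d)), seed=seed,
        )

    def test_exact_counts_with_ten_nodes_per_class(self):
        cohort = self._cohort()
        train, test = grouped_stratified_split(cohort, 0.2, seed=0)
        test_nodes = set(m.node_id for m in test.meta)
        assert len(test_nodes) == 6  # 2 per class
        per_class = {}
        for m in test.meta:
            per_class.setdefault(m.label, set()).add(m.node_id)
        assert all(len(v) == 2 for v in per_class.values())

    def test_no_node_straddles_the_split_and_rows_partition(self):
        cohort = self._cohort()
        train, test = grouped_stratified_split(cohort, 0.2, seed=1)
        assert not (set(m.node_id for m in train.meta)
                    & set(m.node_id for m in test.meta))
        assert train.n + test.n == cohort.n

    def test_seed_determinism_and_variation(self):
        cohort = self._cohort()
        a1 = grouped_stratified_split(cohort, 0.2, seed=5)[1]
        a2 = grouped_stratified_split(cohort, 0.2, seed=5)[1]
        assert [m.node_id for m in a1.meta] == [m.node_id for m in a2.meta]
        variants = {
            frozenset(m.node_id for m in
                      grouped_stratified_split(cohort, 0.2, seed=s)[1].meta)
            for s in range(20)
        }
        assert len(variants) > 1

    def test_single_node_class_is_stratification_error(self):
        def label_of(i):
            return "ecs" if i == 0 else ("reactive", "pathologic")[i % 2]

        cohort = make_grouped_cohort(
            7, 2, 3, label_of, lambda rng, n, d: rng.standard_normal((n, d))
        )
        with pytest.raises(StratificationError, match="single node"):
            grouped_stratified_split(cohort, 0.2, seed=0)
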