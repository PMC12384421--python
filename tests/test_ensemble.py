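"""Class-specific one-vs-rest ensemble: voting, calibration, evaluation."""

import numpy as np
import pytest

from radefs.classifiers import ClassifierSpec
from radefs.cohort import Cohort
from radefs.ensemble import evaluate_ensemble, fit_ensemble
from radefs.evaluation import auc_ovr
from radefs.preprocessing import grouped_stratified_split

from conftest import make_grouped_cohort


def _separable_cohort(seed=0, n_nodes=45, d=6):
    """Each class shifted along its own feature; trivially separable."""

    def label_of(i):
        return ("reactive", "pathologic", "ecs")[i % 3]

    def X_fn(rng, n, dd):
        X = rng.standard_normal((n, dd)) * 0.2
        for i in range(n):
            X[i, (i // 3) % 3] += 8.0  # node i//3, class (i//3)%3 -> feature
        return X

    return make_grouped_cohort(n_nodes, 3, d, label_of, X_fn, seed=seed)


def _per_class(cohort, p=2):
    names = list(cohort.manifest.names)
    return {
        "reactive": (names[:p], ClassifierSpec("lda")),
        "pathologic": (names[1:1 + p], ClassifierSpec("lda")),
        "ecs": (names[2:2 + p], ClassifierSpec("lda")),
    }


class TestFitPredict:
    def test_separable_cohort_perfect_training_bacc(self):
        cohort = _separable_cohort()
        ens = fit_ensemble(cohort, _per_class(cohort), seed=0)
        ev = evaluate_ensemble(ens, cohort)
        assert ev.macro_bacc == 1.0
        assert np.all(ev.confusion == np.diag(ev.confusion.diagonal()))

    def test_refit_same_seed_reproduces_probabilities(self):
        cohort = _separable_cohort(seed=1)
        a = fit_ensemble(cohort, _per_class(cohort), seed=3)
        b = fit_ensemble(cohort, _per_class(cohort), seed=3)
        pa, ca = a.predict(cohort)
        pb, cb = b.predict(cohort)
        assert pa.tolist() == pb.tolist()
        np.testing.assert_array_equal(ca, cb)

    def test_confidences_renormalized_to_unit_sum(self):
        cohort = _separable_cohort(seed=2)
        ens = fit_ensemble(cohort, _per_class(cohort), seed=0)
        _, conf = ens.predict(cohort)
        np.testing.assert_allclose(conf.sum(axis=1), 1.0, atol=1e-9)

    def test_argmax_and_severity_tie_break(self):
        cohort = _separable_cohort(seed=3)
        ens = fit_ensemble(cohort, _per_class(cohort), seed=0)
        sev = {c: i for i, c in enumerate(ens.severity)}
        conf, classes = ens.confidences(cohort)
        labels, _ = ens.predict(cohort)
        for row, lab in zip(conf, labels):
            tied = [classes[j] for j in np.flatnonzero(row == row.max())]
            assert lab == min(tied, key=lambda c: sev[c])
        # explicit tie: equal confidences resolve to the more severe class
        assert ens.severity.index("ecs") < ens.severity.index("pathologic")
        assert ens.severity.index("pathologic") < ens.severity.index("reactive")

    def test_unused_feature_removal_does_not_change_predictions(self):
        cohort = _separable_cohort(seed=4, d=8)
        per_class = _per_class(cohort)  # uses features 0..3 only
        ens = fit_ensemble(cohort, per_class, seed=0)
        used = ens.required_features()
        reduced = cohort.select_features(used)
        p_full, c_full = ens.predict(cohort)
        p_red, c_red = ens.predict(reduced)
        assert p_full.tolist() == p_red.tolist()
        np.testing.assert_array_equal(c_full, c_red)

    def test_missing_feature_error_names_the_feature(self):
        cohort = _separable_cohort(seed=5)
        ens = fit_ensemble(cohort, _per_class(cohort), seed=0)
        names = list(cohort.manifest.names)
        crippled = cohort.select_features(names[3:])
        with pytest.raises(KeyError, match="firstorder_F0"):
            ens.predict(crippled)

    def test_missing_class_configuration_rejected(self):
        cohort = _separable_cohort(seed=6)
        per_class = _per_class(cohort)
        del per_class["ecs"]
        with pytest.raises(ValueError, match="ecs"):
            fit_ensemble(cohort, per_class, seed=0)


class TestEvaluate:
    def test_confusion_rows_sum_to_class_test_counts(self):
        cohort = _separable_cohort(seed=7)
        train, test = grouped_stratified_split(cohort, 0.25, seed=0)
        ens = fit_ensemble(train, _per_class(train), seed=0)
        ev = evaluate_ensemble(ens, test)
        y = test.labels
        for i, cls in enumerate(ev.classes):
            assert ev.confusion[i].sum() == int((y == cls).sum())

    def test_reported_auc_consistent_with_metric_function(self):
        cohort = _separable_cohort(seed=8)
        train, test = grouped_stratified_split(cohort, 0.25, seed=1)
        ens = fit_ensemble(train, _per_class(train), seed=0)
        ev = evaluate_ensemble(ens, test)
        conf, classes = ens.confidences(test)
        y = test.labels
        for j, cls in enumerate(classes):
            t_bin = np.where(y == cls, cls, "rest").astype(object)
            expected = auc_ovr(t_bin, conf[:, j], positive=cls)
            assert ev.per_class[cls]["auc"] == pytest.approx(expected)

    def test_summary_reports_range_mean_sd_across_classes(self):
        cohort = _separable_cohort(seed=9)
        train, test = grouped_stratified_split(cohort, 0.25, seed=2)
        ens = fit_ensemble(train, _per_class(train), seed=0)
        ev = evaluate_ensemble(ens, test)
        for m in ("bacc", "auc", "f1"):
            vals = [ev.per_class[c][m] for c in ev.classes]
            assert ev.summary[m]["min"] == pytest.approx(min(vals))
            assert ev.summary[m]["max"] == pytest.approx(max(vals))
            assert ev.summary[m]["mean"] == pytest.approx(np.mean(vals))
            assert ev.summary[m]["sd"] == pytest.approx(np.std(vals))
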