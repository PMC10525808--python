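"""Classifier benchmark: metrics, CV schemes, models."""

import numpy as np
import pandas as pd
import pytest

from emgrisk import (MODEL_SPECS, NO_RISK, RISK, ParameterError, auc_roc,
                     evaluate_confusion, leave_one_subject_out, make_model,
                     minmax_normalize, run_benchmark, stratified_kfold)
from emgrisk.mlbench import confusion_matrix_counts
from emgrisk.spectral import FEATURE_COLUMNS


def brute_force_auc(scores, labels, positive=NO_RISK):
    """Oracle: exhaustive pairwise comparison, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluateConfusion:
    def test_perfect_diagonal_gives_all_ones(self):
        m = evaluate_confusion(np.array([[50, 0], [0, 50]]))
        for key in ("accuracy", "f_measure", "specificity", "sensitivity",
                    "precision", "recall"):
            assert m[key] == 1.0

    def test_all_one_class_prediction_zeroes_one_rate(self):
        m = evaluate_confusion(np.array([[50, 0], [50, 0]]))
        assert m["specificity"] == 0.0
        assert m["sensitivity"] == 1.0

    def test_zero_denominator_reported_missing(self):
        m = evaluate_confusion(np.array([[0, 0], [3, 7]]))
        assert m["sensitivity"] is None

    def test_recall_equals_sensitivity_and_f_is_harmonic_mean(self, rng):
        c = rng.integers(1, 100, size=(2, 2))
        m = evaluate_confusion(c)
        assert m["recall"] == m["sensitivity"]
        expected_f = 2 * m["precision"] * m["recall"] / (m["precision"]
                                                         + m["recall"])
        assert m["f_measure"] == pytest.approx(expected_f, abs=1e-12)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ParameterError):
            evaluate_confusion(np.zeros((3, 2)))


class TestMinmaxNormalize:
    def test_midpoint_maps_to_half(self):
        train = np.array([[0.0], [10.0]])
        _, out = minmax_normalize(train, np.array([[5.0]]))
        assert out[0, 0] == 0.5

    def test_outside_train_range_not_clipped(self):
        train = np.array([[0.0], [10.0]])
        _, out = minmax_normalize(train, np.array([[-5.0], [20.0]]))
        assert out[0, 0] == -0.5
        assert out[1, 0] == 2.0

    def test_constant_train_column_maps_to_zero(self):
        train = np.full((4, 1), 3.0)
        t, a = minmax_normalize(train, np.array([[7.0]]))
        assert np.all(t == 0.0) and np.all(a == 0.0)

    def test_statistics_come_from_train_rows_only(self):
        """Leakage guard: the transform of a fixed train set must not
        depend on the rows it is applied to."""
        train = np.array([[0.0], [2.0]])
        _, a = minmax_normalize(train, np.array([[1.0]]))
        _, b = minmax_normalize(train, np.array([[1.0], [100.0], [-50.0]]))
        assert a[0, 0] == b[0, 0] == 0.5


class TestCvSchemes:
    def test_stratified_fold_balance_246_per_class(self):
        labels = np.array([NO_RISK] * 246 + [RISK] * 246)
        assignment = stratified_kfold(labels, k=10, seed=0)
        for fold in range(10):
            for cls in (NO_RISK, RISK):
                count = np.sum((assignment == fold) & (labels == cls))
                assert count in (24, 25)

    def test_fold_assignment_deterministic(self):
        labels = np.array([NO_RISK, RISK] * 30)
        a = stratified_kfold(labels, k=10, seed=7)
        b = stratified_kfold(labels, k=10, seed=7)
        assert np.array_equal(a, b)

    def test_two_fold_on_four_balanced_instances(self):
        labels = np.array([NO_RISK, NO_RISK, RISK, RISK])
        assignment = stratified_kfold(labels, k=2, seed=0)
        for fold in (0, 1):
            idx = assignment == fold
            assert sorted(labels[idx]) == [NO_RISK, RISK]

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([NO_RISK] * 3 + [RISK] * 20)
        with pytest.raises(ParameterError):
            stratified_kfold(labels, k=10)

    def test_loso_is_a_partition_by_subject(self):
        subjects = np.repeat([f"S{i}" for i in range(8)], 5)
        splits = leave_one_subject_out(subjects)
        assert len(splits) == 8
        tested = []
        for train, test in splits:
            assert set(subjects[train]).isdisjoint(set(subjects[test]))
            assert len(set(subjects[test])) == 1
            tested.extend(test)
        assert sorted(tested) == list(range(len(subjects)))

    def test_single_subject_rejected(self):
        with pytest.raises(ParameterError):
            leave_one_subject_out(np.array(["S1", "S1"]))


class TestAucRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([NO_RISK, NO_RISK, RISK, RISK])
        assert auc_roc(scores, labels) == 1.0

    def test_matches_brute_force_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = rng.integers(0, 5, size=n).astype(float)  # many ties
            labels = rng.choice([NO_RISK, RISK], size=n)
            if len(set(labels)) < 2:
                continue
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(1000)
        labels = rng.choice([NO_RISK, RISK], size=1000)
        assert auc_roc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            auc_roc(np.array([1.0, 2.0]), np.array([RISK, RISK]))


class TestMakeModel:
    def test_svm_separates_separable_toy_set(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([NO_RISK, RISK])
        model = make_model(MODEL_SPECS["SVM"]).fit(X, y)
        assert list(model.predict(X)) == list(y)

    def test_knn_majority_rule(self):
        X = np.vstack([np.zeros((11, 2)), np.ones((11, 2)) * 5])
        y = np.array([NO_RISK] * 11 + [RISK] * 11)
        model = make_model(MODEL_SPECS["KNN"]).fit(X, y)
        assert model.predict([[0.1, 0.1]])[0] == NO_RISK

    def test_gbt_zero_learning_rate_predicts_prior_class(self):
        import dataclasses
        spec = MODEL_SPECS["GBT"]
        degenerate = dataclasses.replace(
            spec, hyperparameters={**spec.hyperparameters,
                                   "learning_rate": 0.0})
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = np.array([NO_RISK] * 20 + [RISK] * 10)
        model = make_model(degenerate).fit(X, y)
        assert set(model.predict(X)) == {NO_RISK}  # majority prior

    def test_nb_variance_floor_applied(self):
        X = np.array([[0.0], [1e-6], [1.0], [1.0 + 1e-6]])
        y = np.array([NO_RISK, NO_RISK, RISK, RISK])
        model = make_model(MODEL_SPECS["NB"]).fit(X, y)
        assert np.all(model.var_ >= 0.068 ** 2)

    def test_unknown_model_rejected(self):
        from emgrisk import ModelSpec
        with pytest.raises(ParameterError):
            make_model(ModelSpec("RF"))

    def test_normalization_flags(self):
        needs = {name for name, spec in MODEL_SPECS.items()
                 if spec.needs_normalization}
        assert needs == {"LR", "KNN", "SVM"}


def toy_feature_table(n_subjects=4, lifts=8, separation=2.0, seed=0):
    """Small learnable table with per-subject structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject_shift = rng.normal(0, 0.3)
        for lift in range(lifts):
            for cond, d in ((NO_RISK, 0.0), (RISK, separation)):
                row = {"subject_id": f"S{s}", "lift_index": lift,
                       "label": cond}
                for i, col in enumerate(FEATURE_COLUMNS):
                    row[col] = rng.normal(subject_shift + (d if i < 4 else 0),
                                          1.0)
                rows.append(row)
    return pd.DataFrame(rows)


class TestRunBenchmark:
    def test_results_shape_and_confusion_conservation(self):
        table = toy_feature_table()
        results = run_benchmark(table, schemes=("tenfold",), seed=0, k=4)
        assert len(results) == 6
        for res in results:
            assert res.confusion.sum() == len(table)
            for value in res.metrics.values():
                if value is not None:
                    assert 0.0 <= value <= 1.0

    def test_identical_seed_identical_results(self):
        table = toy_feature_table()
        a = run_benchmark(table, schemes=("tenfold",), seed=5, k=4,
                          models=("SVM", "GBT"))
        b = run_benchmark(table, schemes=("tenfold",), seed=5, k=4,
                          models=("SVM", "GBT"))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.confusion, rb.confusion)
            assert ra.metrics == rb.metrics

    def test_loso_reports_per_fold_and_mean_std(self):
        table = toy_feature_table()
        res = run_benchmark(table, schemes=("loso",), seed=0,
                            models=("KNN",))[0]
        assert len(res.per_fold) == 4
        assert res.metrics_std is not None
        accs = [f["accuracy"] for f in res.per_fold]
        assert res.metrics["accuracy"] == pytest.approx(np.mean(accs))

    def test_missing_columns_rejected(self):
        with pytest.raises(ParameterError):
            run_benchmark(pd.DataFrame({"label": []}))

    def test_label_copy_feature_with_fold_fitted_normalization(self):
        """Leakage probe: a feature that encodes the label must be fully
        learnable (fit on train folds only is still enough), while pure
        noise features are not — confirming normalization statistics do
        not leak test information into training."""
        table = toy_feature_table(separation=0.0)
        table[FEATURE_COLUMNS[0]] = (table["label"] == NO_RISK) * 1.0
        res = run_benchmark(table, schemes=("tenfold",), seed=0, k=4,
                            models=("KNN",))[0]
        assert res.metrics["accuracy"] == 1.0

    def test_confusion_matrix_counts_layout(self):
        y_true = np.array([NO_RISK, NO_RISK, RISK, RISK, RISK])
        y_pred = np.array([NO_RISK, RISK, RISK, RISK, NO_RISK])
        c = confusion_matrix_counts(y_true, y_pred)
        assert c.tolist() == [[1, 1], [1, 2]]
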