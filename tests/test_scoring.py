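import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gawcc.candidates import CandidateSolution
from gawcc.datasets import FeatureTable
from gawcc.scoring import (
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    evaluate_subset,
    make_cv_plan,
    panel_from_predictions,
    panel_metrics,
    regression_metrics,
    roc_auc,
)


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(50, 40, 5, 5), 0.9),
            (ConfusionCounts(0, 0, 1, 1), 0.0),
            (ConfusionCounts(7, 3, 0, 0), 1.0),
        ],
    )
    def test_formula(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts(0, 0, 0, 0))


class TestPanelMetrics:
    def test_binary_arithmetic(self):
        panel = panel_metrics(ConfusionCounts(tp=9, tn=9, fp=1, fn=1))
        for key, value in [
            ("SEN", 0.9), ("SPC", 0.9), ("PRE", 0.9), ("FPR", 0.1),
            ("ACC", 0.9), ("F_measure", 0.9),
        ]:
            assert panel[key] == pytest.approx(value, abs=1e-12)

    def test_acc_consistent_with_accuracy(self):
        counts = ConfusionCounts(tp=13, tn=22, fp=4, fn=7)
        assert panel_metrics(counts)["ACC"] == accuracy(counts)

    def test_zero_denominator_reported_as_zero_with_warning(self):
        counts = ConfusionCounts(tp=0, tn=5, fp=0, fn=5)
        with pytest.warns(UserWarning, match="PRE"):
            panel = panel_metrics(counts)
        assert panel["PRE"] == 0.0

    def test_perfect_binary_kappa(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        panel = panel_from_predictions(y, y)
        assert panel["C_kappa"] == pytest.approx(1.0, abs=1e-12)

    def test_three_class_kappa_matches_hand_computation(self):
        # 20-sample confusion table (rows true A,B,C / cols pred):
        #   A: 5 1 0 | B: 1 6 1 | C: 0 1 5
        # p_o = 16/20 = 0.8; marginals both (6, 8, 6)
        # p_e = (36 + 64 + 36) / 400 = 0.34
        # kappa = (0.8 - 0.34) / 0.66 = 46/66
        y_true = ["A"] * 6 + ["B"] * 8 + ["C"] * 6
        y_pred = (
            ["A"] * 5 + ["B"]
            + ["A"] + ["B"] * 6 + ["C"]
            + ["B"] + ["C"] * 5
        )
        panel = panel_from_predictions(np.array(y_true), np.array(y_pred))
        assert panel["C_kappa"] == pytest.approx(46 / 66, abs=1e-12)
        assert panel["ACC"] == pytest.approx(0.8, abs=1e-12)


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_pure_ties(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        wins = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in scores[labels == 1]
            for sn in scores[labels == 0]
        )
        expected = wins / 4  # = 0.75
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_strictly_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.array([0] * 10 + [1] * 10)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) + 2, labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestRegressionMetrics:
    def test_identity(self):
        out = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["RMSE"] == pytest.approx(0.0, abs=1e-12)
        assert out["correlation"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift(self):
        real = np.array([1.0, 2.0, 3.0, 4.0])
        out = regression_metrics(real + 1, real)
        assert out["RMSE"] == pytest.approx(1.0, abs=1e-12)
        assert out["correlation"] == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self):
        real = np.array([1.0, 2.0, 5.0])
        assert regression_metrics(-real, real)["correlation"] == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_constant_real_labels_undefined(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics([1.0, 2.0], [3.0, 3.0])


class TestEvaluateSubset:
    def test_separable_feature_reaches_full_accuracy(
        self, separable_table, separable_plan
    ):
        res = evaluate_subset(
            separable_table, CandidateSolution.from_values([1]), separable_plan
        )
        assert res.fitness == 1.0
        assert res.metrics["ACC"] == 1.0
        assert res.metrics["AUC"] == 1.0
        assert res.nof == 1

    def test_out_of_range_index_rejected(self, separable_table, separable_plan):
        cs = CandidateSolution.from_values([1, 99])
        with pytest.raises(ValueError, match="exceeds"):
            evaluate_subset(separable_table, cs, separable_plan)

    def test_null_tables_score_near_chance(self):
        # labels independent of the feature: CV accuracy stays in a band
        # around 0.5 (band frozen from a 100-table simulation of the null)
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            matrix = rng.normal(size=(n, 1))
            labels = np.array([0, 1] * (n // 2))
            table = FeatureTable(matrix, labels, ("f1",), "classification")
            plan = make_cv_plan(table, 5, seed)
            res = evaluate_subset(
                table, CandidateSolution.from_values([1]), plan, with_panel=False
            )
            accs.append(res.fitness)
        assert all(0.35 <= a <= 0.65 for a in accs)

    def test_deterministic_given_seed(self, separable_table, separable_plan):
        cs = CandidateSolution.from_values([1, 3, 5])
        a = evaluate_subset(separable_table, cs, separable_plan)
        b = evaluate_subset(separable_table, cs, separable_plan)
        assert a.fitness == b.fitness
        assert a.metrics == b.metrics

    def test_fold_imputation_handles_missing(self, separable_table, separable_plan):
        matrix = separable_table.matrix.copy()
        matrix[::7, 1] = np.nan
        table = FeatureTable(
            matrix,
            separable_table.labels,
            separable_table.feature_names,
            "classification",
        )
        res = evaluate_subset(table, CandidateSolution.from_values([1, 2]), separable_plan)
        assert np.isfinite(res.fitness)

    def test_regression_fitness_is_negative_rmse(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 2))
        y = x[:, 0] * 2 + rng.normal(0, 0.1, 80)
        table = FeatureTable(x, y, ("f1", "f2"), "regression")
        plan = make_cv_plan(table, 5, 0)
        res = evaluate_subset(table, CandidateSolution.from_values([1]), plan)
        assert res.fitness == pytest.approx(-res.metrics["RMSE"])
        assert res.metrics["correlation"] > 0.9


class TestCvPlan:
    def test_folds_partition_and_balance(self, separable_table):
        plan = make_cv_plan(separable_table, k=5, seed=2)
        sizes = np.bincount(plan.fold_ids, minlength=5)
        assert sizes.sum() == separable_table.n_samples
        assert sizes.max() - sizes.min() <= 1

    def test_stratified_by_label(self, separable_table):
        plan = make_cv_plan(separable_table, k=5, seed=2)
        y = separable_table.labels
        for f in range(5):
            fold_labels = y[plan.fold_ids == f]
            # 30/30 split, 12 per fold -> exactly 6 of each class
            assert (fold_labels == "pos").sum() == 6

    def test_training_fold_missing_class_detected(self):
        matrix = np.arange(10, dtype=float).reshape(-1, 1)
        labels = np.array(["a"] * 9 + ["b"])
        table = FeatureTable(matrix, labels, ("f1",), "classification")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on tiny classes
            plan = make_cv_plan(table, 5, 0)
        with pytest.raises(UndefinedMetricError, match="missing a class"):
            evaluate_subset(table, CandidateSolution.from_values([1]), plan)
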