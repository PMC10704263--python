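"""Grouped cross-validation, majority voting, metrics, feature ranking and
greedy outlier elimination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarlr import ml
from polarlr.decomposition import FEATURE_NAMES


def _toy_cohort(n_pat0=10, n_pat1=6, rois=4, informative=("delta_L", "D"), gap=3.0, seed=0):
    """Small cohort table with two planted informative features, rest noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for c, n in ((0, n_pat0), (1, n_pat1)):
        for i in range(n):
            pid = f"c{c}p{i}"
            shift = {f: c * gap + rng.normal(0, 0.3) for f in informative}
            for r in range(rois):
                row = {"patient_id": pid, "roi_id": f"{pid}r{r}", "label": c}
                for f in FEATURE_NAMES:
                    base = shift.get(f, 0.0)
                    row[f] = base + rng.normal(0, 1.0)
                rows.append(row)
    return pd.DataFrame(rows)


class TestGroupedKFold:
    def test_35_patients_five_folds_of_seven(self):
        labels = {f"p{i}": (0 if i < 27 else 1) for i in range(35)}
        plan = ml.grouped_kfold(labels, 5, seed=0)
        assert sorted(len(f) for f in plan.folds) == [7] * 5
        # stratification: every fold gets 1-2 of the 8 minority patients
        minority = {p for p, l in labels.items() if l == 1}
        per_fold = [len(minority & set(f)) for f in plan.folds]
        assert sorted(per_fold) == [1, 1, 2, 2, 2]

    def test_ten_patients_k5_folds_of_two(self):
        labels = {f"p{i}": i % 2 for i in range(10)}
        plan = ml.grouped_kfold(labels, 5, seed=1)
        assert all(len(f) == 2 for f in plan.folds)

    def test_no_leakage_exhaustive(self):
        for seed, n, k in itertools.product(range(5), (11, 23, 35), (2, 3, 5)):
            labels = {f"p{i}": (i % 4 == 0) * 1 for i in range(n)}
            plan = ml.grouped_kfold(labels, k, seed)
            plan.validate()
            seen = set()
            for i in range(k):
                train, test = plan.train_test(i)
                assert not set(train) & set(test)
                seen |= set(test)
            assert seen == set(labels)

    def test_k_exceeding_patients_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            ml.grouped_kfold({"a": 0, "b": 1}, 5, 0)

    def test_fold_sizes_differ_at_most_one(self):
        labels = {f"p{i}": (0 if i < 27 else 1) for i in range(33)}
        plan = ml.grouped_kfold(labels, 5, seed=3)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1


class TestMajorityVote:
    @pytest.mark.parametrize(
        "preds,expected",
        [
            ([1, 1, 1, 1, 0, 0, 0, 0], 1),  # exact tie -> LR
            ([0, 0, 0, 0, 0], 0),
            ([1, 1, 1, 0, 0], 1),
        ],
    )
    def test_threshold_semantics(self, preds, expected):
        assert ml.majority_vote(preds) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ml.majority_vote([])

    @given(st.lists(st.sampled_from([0, 1]), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_unanimous_predictions_fix_the_call(self, preds):
        if len(set(preds)) == 1:
            assert ml.majority_vote(preds) == preds[0]
        else:
            assert ml.majority_vote(preds) in (0, 1)


class TestMetrics:
    def test_arithmetic(self):
        cm = np.array([[5, 1], [1, 3]])  # TN=5 FP=1 FN=1 TP=3
        m = ml.performance_metrics(cm)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_perfect_prediction(self):
        m = ml.performance_metrics(np.array([[4, 0], [0, 4]]))
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 1.0

    def test_degenerate_sensitivity_nan_with_flag(self):
        m = ml.performance_metrics(np.array([[5, 2], [0, 0]]))
        assert np.isnan(m["sensitivity"])
        assert "sensitivity_undefined" in m["flags"]

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            ml.performance_metrics(np.zeros((2, 2)))

    def test_metric_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cm = rng.integers(1, 20, size=(2, 2)).astype(float)
            m = ml.performance_metrics(cm)
            (tn, fp), (fn, tp) = cm
            lhs = m["sensitivity"] * (tp + fn) + m["specificity"] * (tn + fp)
            assert lhs == pytest.approx(tp + tn)


class TestROC:
    def test_perfect_ranking(self):
        _, _, a = ml.roc_and_auroc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert a == 1.0

    def test_auroc_equals_concordant_pair_oracle(self):
        """Tie-corrected AUROC equals the O(n²) Mann–Whitney pair count."""
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            _, _, a = ml.roc_and_auroc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert a == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(123)
        n = 4000
        labels = rng.integers(0, 2, n)
        scores = rng.normal(size=n)
        _, _, a = ml.roc_and_auroc(scores, labels)
        assert 0.45 < a < 0.55

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ml.roc_and_auroc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_mean_roc_grid(self):
        fpr = np.array([0, 0.5, 1.0])
        tpr = np.array([0, 0.8, 1.0])
        out = ml.mean_roc([(fpr, tpr), (fpr, tpr)], [0.9, 0.7])
        assert out["fpr"].shape == (101,)
        assert out["auroc_mean"] == pytest.approx(0.8)
        assert out["tpr"][0] == 0.0 and out["tpr"][-1] == 1.0


class TestTrainModels:
    def test_separable_tree_models_fit_training_data(self):
        df = _toy_cohort(gap=6.0, seed=1)
        X = df[FEATURE_NAMES].to_numpy()
        y = df["label"].to_numpy()
        fitted = ml.train_models(X, y, FEATURE_NAMES, ["random_forest", "xgboost"], seed=0)
        for f in fitted.values():
            assert np.mean(f.predict(X) == y) == 1.0
            assert f.importances().shape == (25,)

    def test_constant_features_no_signal(self):
        X = np.ones((40, 25))
        y = np.array([0, 1] * 20)
        fitted = ml.train_models(X, y, FEATURE_NAMES, ["logistic"], seed=0)
        s = fitted["logistic"].scores(X)
        assert np.allclose(s, s[0])

    def test_single_class_errors(self):
        X = np.zeros((10, 25))
        with pytest.raises(ValueError, match="single class"):
            ml.train_models(X, np.zeros(10), FEATURE_NAMES, ["svm"])


class TestRankFeatures:
    def test_minmax_normalization(self):
        t = ml.rank_features({"m": np.array([2.0, 1.0, 0.0])}, ["a", "b", "c"], k=2)
        np.testing.assert_allclose(t.normalized.loc["m"], [1.0, 0.5, 0.0])
        assert t.selected == ["a", "b"]

    def test_constant_vector_flagged(self):
        t = ml.rank_features({"m": np.ones(3)}, ["a", "b", "c"], k=1)
        assert np.all(t.normalized.loc["m"] == 0)
        assert any("constant" in f for f in t.flags)

    def test_tie_breaks_by_name(self):
        t = ml.rank_features({"m": np.array([1.0, 1.0, 0.0])}, ["z", "a", "c"], k=2)
        assert t.selected == ["a", "z"]

    def test_k_selection_size(self):
        rng = np.random.default_rng(0)
        t = ml.rank_features({"m": rng.random(25)}, FEATURE_NAMES, k=5)
        assert len(t.selected) == 5

    def test_planted_informative_features_recovered(self):
        for seed in (0, 1, 2):
            df = _toy_cohort(gap=4.0, seed=seed)
            reports = ml.run_experiment(df, ["xgboost", "random_forest"], k=3, seed=seed)
            t = ml.rank_features(
                {m: r.importances_mean for m, r in reports.items()}, FEATURE_NAMES, k=5
            )
            assert {"delta_L", "D"} <= set(t.selected), (seed, t.selected)


class TestExperiment:
    def test_determinism_same_seed(self, separable_cohort):
        feats, _, _ = separable_cohort
        r1 = ml.run_experiment(feats, ["xgboost"], k=5, seed=3)["xgboost"]
        r2 = ml.run_experiment(feats, ["xgboost"], k=5, seed=3)["xgboost"]
        assert r1.auroc_mean == r2.auroc_mean
        np.testing.assert_array_equal(r1.mean_cm_patient, r2.mean_cm_patient)
        np.testing.assert_array_equal(r1.folds[0].roi_scores, r2.folds[0].roi_scores)

    def test_vote_consistency_in_folds(self, separable_cohort):
        feats, _, _ = separable_cohort
        rep = ml.run_experiment(feats, ["xgboost"], k=5, seed=3)["xgboost"]
        for fold in rep.folds:
            test_df = feats[feats["patient_id"].isin(fold.patient_ids)]
            for pid, call in zip(fold.patient_ids, fold.patient_pred):
                mask = test_df["patient_id"] == pid
                preds = fold.roi_pred[
                    test_df.reset_index(drop=True).index[
                        test_df.reset_index(drop=True)["patient_id"] == pid
                    ]
                ]
                if len(set(preds)) == 1:
                    assert call == preds[0]

    def test_confusion_totals(self, separable_cohort):
        feats, _, _ = separable_cohort
        rep = ml.run_experiment(feats, ["logistic"], k=5, seed=2)["logistic"]
        for fold in rep.folds:
            assert fold.cm_roi.sum() == len(fold.roi_true)
            assert fold.cm_patient.sum() == len(fold.patient_ids)

    def test_single_class_cohort_errors(self):
        df = _toy_cohort(n_pat1=6, seed=0)
        df["label"] = 0
        with pytest.raises(ValueError, match="single class"):
            ml.run_experiment(df, ["xgboost"], k=3, seed=0)


class TestEliminateOutliers:
    def test_clean_cohort_no_removals(self, separable_cohort):
        feats, _, _ = separable_cohort
        _, log = ml.eliminate_outliers(feats, budget=2, k=5, seed=1)
        assert log == []

    def test_removal_log_within_budget(self):
        df = _toy_cohort(n_pat0=14, n_pat1=8, gap=1.0, seed=4)
        _, log = ml.eliminate_outliers(df, budget=2, k=5, seed=0, n_repeats=1)
        assert len(log) <= 2
        for entry in log:
            assert entry["auroc_after"] > entry["auroc_before"]

    def test_infeasible_budget_errors(self):
        df = _toy_cohort(n_pat0=8, n_pat1=4, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            ml.eliminate_outliers(df, budget=5, k=5)


class TestFullWorkflow:
    def test_report_structure_and_subgroup(self, separable_cohort):
        feats, pats, _ = separable_cohort
        t_stage = dict(zip(pats["patient_id"], pats["t_stage"]))
        res = ml.run_full_workflow(
            feats, ["xgboost"], k=3, seed=1, t_stage=t_stage, t_stage_subgroup=3
        )
        assert set(res) >= {"all_features", "top_features", "importance_table", "removal_log"}
        assert len(res["importance_table"].selected) == 5
        rep = res["top_features"]["xgboost"]
        assert 0 <= rep.auroc_mean <= 1
        assert rep.mean_cm_patient.sum() * 3 == pytest.approx(21)  # 21 patients over 3 folds
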