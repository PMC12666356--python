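"""Harness: splits, metric identities, folds, PCA baseline, ablation."""

import numpy as np
import pytest

from rfgr.data import SEGMENT_LENGTH, SegmentDataset
from rfgr.evaluation import (
    CVReport,
    StratificationError,
    ablation_table,
    build_features,
    evaluate_classifier,
    kfold_cv,
    pca_baseline,
    report_from_predictions,
    runtime_profile,
    split_indices,
    stratified_split,
)
from rfgr.features import RFGRConfig
from rfgr.models import ClassifierSpec, fit_spec


class TestStratifiedSplit:
    def test_80_20_preserves_class_proportions(self, small_dataset):
        train, test = stratified_split(small_dataset, 0.8, seed=0)
        assert len(train) + len(test) == len(small_dataset)
        for code in range(1, 6):
            n_test = int((test.y == code).sum())
            assert abs(n_test - 0.2 * (small_dataset.y == code).sum()) <= 1

    def test_partition_is_disjoint_and_exhaustive(self, small_dataset):
        idx_tr, idx_te = split_indices(small_dataset.y, 0.8, seed=1)
        union = np.sort(np.concatenate([idx_tr, idx_te]))
        assert np.array_equal(union, np.arange(len(small_dataset)))

    def test_full_train_fraction_gives_empty_test(self, small_dataset):
        train, test = stratified_split(small_dataset, 1.0, seed=0)
        assert len(test) == 0 and len(train) == len(small_dataset)

    def test_class_with_single_row_rejected(self):
        X = np.zeros((3, SEGMENT_LENGTH))
        ds = SegmentDataset(X, [1, 1, 2])
        with pytest.raises(StratificationError):
            stratified_split(ds, 0.5, seed=0)


class TestMetricIdentities:
    def test_perfect_predictions_give_all_ones(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        rep = report_from_predictions(y, y)
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert all(m["f1"] == 1.0 for m in rep.per_class.values())

    def test_hand_computed_two_class_confusion(self):
        """Confusion [[3,1],[2,4]]: acc 0.7; class-0 p=0.6 r=0.75 f1~=0.6667."""
        y_true = np.array([1] * 4 + [2] * 6)
        y_pred = np.array([1, 1, 1, 2, 1, 1, 2, 2, 2, 2])
        rep = report_from_predictions(y_true, y_pred)
        assert np.array_equal(rep.confusion, [[3, 1], [2, 4]])
        assert rep.accuracy == pytest.approx(0.7)
        m = rep.per_class[1]
        assert m["precision"] == pytest.approx(0.6)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_macro_rows_equal_per_class_means(self, toy_features):
        X, y = toy_features
        rep = evaluate_classifier(fit_spec(ClassifierSpec("gnb"), X, y), X, y)
        per = rep.per_class
        assert rep.macro_f1 == pytest.approx(
            np.mean([per[c]["f1"] for c in rep.class_codes])
        )
        table = rep.to_frame()
        avg = table[table["target class"] == "Average"].iloc[0]
        body = table[table["target class"] != "Average"]
        assert avg["precision"] == pytest.approx(body["precision"].mean())

    def test_confusion_conservation(self, toy_features):
        X, y = toy_features
        rep = evaluate_classifier(fit_spec(ClassifierSpec("gnb"), X, y), X, y)
        assert rep.confusion.sum() == len(y)
        for i, code in enumerate(rep.class_codes):
            assert rep.confusion[i].sum() == (y == code).sum()
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )

    def test_class_absent_from_truth_scores_zero_with_warning(self, toy_features):
        X, y = toy_features
        fitted = fit_spec(ClassifierSpec("gnb"), X, y)
        keep = y != 3
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate_classifier(fitted, X[keep], y[keep])
        assert rep.per_class[3]["recall"] == 0.0


class TestKFold:
    def test_fold_sizes_and_hand_arithmetic(self, small_dataset, tiny_config):
        report = kfold_cv(
            small_dataset, ClassifierSpec("gnb"), "original", k=5, config=tiny_config
        )
        assert len(report.fold_accuracies) == 5
        accs = np.asarray(report.fold_accuracies)
        assert report.mean == pytest.approx(accs.mean(), abs=1e-12)
        assert report.std == pytest.approx(accs.std(), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_folds_partition_for_all_k(self, small_dataset, k):
        from sklearn.model_selection import StratifiedKFold

        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=0)
        sizes = [len(te) for _, te in cv.split(small_dataset.X, small_dataset.y)]
        assert sum(sizes) == len(small_dataset)
        assert max(sizes) - min(sizes) <= 1

    def test_memorizing_model_on_duplicated_rows_scores_one_everywhere(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, SEGMENT_LENGTH))
        X = np.tile(base, (4, 1))
        y = np.tile(np.repeat([1, 2], 5), 4)
        ds = SegmentDataset(X, y)
        rep = kfold_cv(ds, ClassifierSpec("rf", {"n_estimators": 20}), "original", k=4)
        assert rep.fold_accuracies == [1.0] * 4
        assert rep.std == 0.0

    def test_k_larger_than_dataset_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            kfold_cv(small_dataset.subset(range(5)), ClassifierSpec("gnb"), "original", k=9)

    def test_class_smaller_than_k_rejected(self):
        ds = SegmentDataset(np.zeros((6, SEGMENT_LENGTH)), [1, 1, 1, 1, 2, 2])
        with pytest.raises(StratificationError):
            kfold_cv(ds, ClassifierSpec("gnb"), "original", k=3)


class TestPCABaseline:
    def test_default_projection_width(self, small_dataset):
        train, test = stratified_split(small_dataset, 0.8, seed=0)
        tr, te, ratios = pca_baseline(train.X, test.X, 20)
        assert tr.shape[1] == te.shape[1] == 20
        assert ratios.shape == (20,)

    def test_full_rank_captures_all_variance(self, small_dataset):
        X = small_dataset.X  # 345 rows > 178 features, full rank
        _, _, ratios = pca_baseline(X, X[:0], SEGMENT_LENGTH)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)

    def test_component_variances_non_increasing(self, small_dataset):
        _, _, ratios = pca_baseline(small_dataset.X, small_dataset.X[:0], 30)
        assert np.all(np.diff(ratios) <= 1e-12)

    def test_excess_components_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            pca_baseline(small_dataset.X, small_dataset.X, SEGMENT_LENGTH + 1)


class TestRuntimeProfileAndAblation:
    def test_profile_returns_nonnegative_seconds(self):
        result, seconds = runtime_profile(sum, [1, 2, 3])
        assert result == 6
        assert seconds >= 0.0

    def test_identical_arms_give_identical_reports(self, toy_features):
        X, y = toy_features
        fitted = fit_spec(ClassifierSpec("gnb"), X, y)
        a = evaluate_classifier(fitted, X, y)
        b = evaluate_classifier(fitted, X, y)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_ablation_table_shape_and_class_names(self, small_dataset, tiny_config):
        table, reports = ablation_table(
            small_dataset,
            ClassifierSpec("rf", {"n_estimators": 20}, seed=0),
            tiny_config,
        )
        assert list(table["feature set"]) == ["original features", "transfer features"]
        for name in (
            "epileptic seizure", "tumor brain area", "healthy brain area",
            "eyes closed", "eyes open",
        ):
            assert name in table.columns
        for arm, rep in reports.items():
            assert table.loc[table["feature set"] == arm, "accuracy"].iloc[0] == rep.accuracy

    def test_unknown_feature_mode_rejected(self, small_dataset, tiny_config):
        train, test = stratified_split(small_dataset, 0.8, 0)
        with pytest.raises(ValueError):
            build_features(train, test, "wavelet", tiny_config)
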