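"""Fusion core: forest probability averaging, temporal heads, leakage safety."""

import numpy as np
import pytest

from rfgr.data import SEGMENT_LENGTH, SegmentDataset
from rfgr.features import (
    DegenerateLabelsError,
    RFGRConfig,
    count_trainable_parameters,
    crossfit_probability_features,
    fit_probability_extractor,
    fit_temporal_extractor,
    generate_transfer_features,
    probability_features,
    temporal_features,
)


def traverse_tree_probability(tree, x):
    """Independent single-tree traversal: leaf class frequencies for x."""
    t = tree.tree_
    node = 0
    while t.children_left[node] != -1:
        if x[t.feature[node]] <= t.threshold[node]:
            node = t.children_left[node]
        else:
            node = t.children_right[node]
    counts = t.value[node, 0, :] * t.weighted_n_node_samples[node]
    return counts / counts.sum()


@pytest.fixture
def toy_two_class():
    """8 rows, 2 well-separated classes, 3 features."""
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 0.5, (4, 3)), rng.normal(8, 0.5, (4, 3))])
    y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return X, y


class TestProbabilityExtractor:
    def test_forest_has_requested_shape(self, toy_two_class):
        X, y = toy_two_class
        ext = fit_probability_extractor(X, RFGRConfig(n_trees=7, max_depth=3), labels=y)
        assert len(ext.trees) == 7
        assert all(t.get_depth() <= 3 for t in ext.trees)

    def test_single_class_train_rejected(self, toy_two_class):
        X, _ = toy_two_class
        with pytest.raises(DegenerateLabelsError):
            fit_probability_extractor(X, RFGRConfig(), labels=np.ones(len(X)))

    def test_single_tree_pure_leaves_on_twinned_toy(self):
        # twin pairs straddle each class so every row lands in a pure leaf
        X = np.array([[0.0], [1.0], [100.0], [101.0]])
        y = np.array([1, 1, 2, 2])
        ext = fit_probability_extractor(X, RFGRConfig(n_trees=1, seed=3), labels=y)
        probs = probability_features(ext, X)
        own = probs[np.arange(4), y - 1]
        assert np.array_equal(own, np.ones(4))

    def test_averaging_matches_independent_traversal(self, toy_two_class):
        """Forest probabilities equal the mean of per-tree leaf frequencies."""
        X, y = toy_two_class
        ext = fit_probability_extractor(X, RFGRConfig(n_trees=3, seed=0), labels=y)
        probe = np.vstack([X, X.mean(axis=0)])
        got = probability_features(ext, probe)
        for i, x in enumerate(probe):
            expected = np.mean(
                [traverse_tree_probability(t, x) for t in ext.trees], axis=0
            )
            assert np.allclose(got[i], expected, atol=1e-12, rtol=0)
        assert np.allclose(got.sum(axis=1), 1.0, atol=1e-9)

    def test_column_order_is_ascending_code(self, toy_two_class):
        X, y = toy_two_class
        ext = fit_probability_extractor(X, RFGRConfig(n_trees=3), labels=y)
        assert list(ext.class_order) == [1, 2]

    def test_width_mismatch_rejected(self, toy_two_class):
        X, y = toy_two_class
        ext = fit_probability_extractor(X, RFGRConfig(n_trees=2), labels=y)
        with pytest.raises(ValueError):
            probability_features(ext, X[:, :2])


@pytest.fixture(scope="module")
def fitted(small_dataset, tiny_config):
    train = small_dataset.subset(range(100))
    return train, fit_temporal_extractor(train, tiny_config)


class TestTemporalExtractor:
    def test_probability_head_rows_sum_to_one(self, fitted, small_dataset):
        _, ext = fitted
        p = temporal_features(ext, small_dataset.subset(range(100, 140)), "probs")
        assert p.shape[1] == len(ext.class_order)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_hidden_head_width_is_units(self, fitted, small_dataset, tiny_config):
        _, ext = fitted
        h = temporal_features(ext, small_dataset.subset(range(20)), "hidden")
        assert h.shape == (20, tiny_config.recurrent_units)

    def test_repeat_inference_bit_identical(self, fitted, small_dataset):
        _, ext = fitted
        probe = small_dataset.subset(range(30))
        assert np.array_equal(
            temporal_features(ext, probe, "probs"),
            temporal_features(ext, probe, "probs"),
        )

    def test_standardization_statistics_come_from_train_only(self, fitted):
        train, ext = fitted
        assert np.allclose(ext.network.mean_, train.X.mean(axis=0), atol=1e-3)

    def test_parameter_count_from_config(self):
        cfg = RFGRConfig()
        layers = dict(count_trainable_parameters(cfg, "gru"))
        assert layers["total"] == layers["gru"] + layers["dense"]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_trees": 0},
            {"n_classes": 1},
            {"cross_fit_folds": 1},
            {"dropout_rate": 1.0},
            {"feature_mode": "bogus"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            RFGRConfig(**kw)


@pytest.fixture(scope="module")
def split(small_dataset):
    n = len(small_dataset)
    return small_dataset.subset(range(0, 250)), small_dataset.subset(range(250, n))


@pytest.fixture(scope="module")
def fused(split, tiny_config):
    train, test = split
    return generate_transfer_features(train, test, tiny_config)


class TestTransferFeatureGeneration:
    def test_fused_mode_has_2k_named_columns(self, fused):
        train_fs, test_fs, _ = fused
        assert train_fs.n_features == 10
        assert train_fs.feature_names == [f"f{i}" for i in range(1, 11)]
        assert train_fs.provenance[:5] == [f"rf_prob:{c}" for c in range(1, 6)]
        assert train_fs.provenance[5:] == [f"gru_prob:{c}" for c in range(1, 6)]
        assert test_fs.X.shape == (test_fs.y.size, 10)

    def test_probability_blocks_row_normalized(self, fused):
        train_fs, test_fs, _ = fused
        for fs, tol in ((train_fs, 1e-6), (test_fs, 1e-6)):
            assert np.allclose(fs.X[:, :5].sum(axis=1), 1.0, atol=tol)
            assert np.allclose(fs.X[:, 5:].sum(axis=1), 1.0, atol=1e-5)

    def test_test_features_invariant_to_test_labels(self, split, tiny_config):
        train, test = split
        _, fs_a, _ = generate_transfer_features(train, test, tiny_config)
        shuffled = SegmentDataset(
            test.X, np.roll(test.y, 7), test.sources, test.chunk_indices
        )
        _, fs_b, _ = generate_transfer_features(train, shuffled, tiny_config)
        assert np.array_equal(fs_a.X, fs_b.X)

    def test_test_features_invariant_to_other_test_rows(self, split, tiny_config):
        train, test = split
        _, full, _ = generate_transfer_features(train, test, tiny_config)
        _, single, _ = generate_transfer_features(train, test.subset([4]), tiny_config)
        assert np.allclose(full.X[4], single.X[0], atol=1e-5)

    def test_generation_is_deterministic(self, split, tiny_config):
        train, test = split
        a_tr, a_te, _ = generate_transfer_features(train, test, tiny_config)
        b_tr, b_te, _ = generate_transfer_features(train, test, tiny_config)
        assert np.array_equal(a_tr.X, b_tr.X)
        assert np.array_equal(a_te.X, b_te.X)

    def test_crossfitting_prevents_memorized_train_probabilities(self, small_dataset):
        """A deep forest memorizes its own rows (own-class prob == 1 in-place);
        the cross-fitted path must show honest uncertainty on some rows."""
        from sklearn.ensemble import RandomForestClassifier

        cfg = RFGRConfig(n_trees=10, cross_fit_folds=3, seed=0)
        train = small_dataset.subset(range(200))
        # refit-in-place with every row visible to every deep tree:
        # unique noisy rows all land in pure own-class leaves
        memorizer = RandomForestClassifier(
            n_estimators=10, bootstrap=False, random_state=0
        ).fit(train.X, train.y)
        own_in_place = memorizer.predict_proba(train.X)[
            np.arange(len(train)), train.y - 1
        ]
        assert np.array_equal(own_in_place, np.ones(len(train)))
        crossed = crossfit_probability_features(train.X, train.y, cfg)
        own_crossed = crossed[np.arange(len(train)), train.y - 1]
        assert own_crossed.min() < 1.0

    def test_empty_train_rejected(self, tiny_config):
        empty = SegmentDataset(np.empty((0, SEGMENT_LENGTH)), [])
        with pytest.raises(ValueError):
            generate_transfer_features(empty, None, tiny_config)

    def test_rf_probs_mode_has_k_columns(self, split):
        train, _ = split
        cfg = RFGRConfig(n_trees=5, cross_fit_folds=2, feature_mode="rf_probs")
        fs, none_fs, _ = generate_transfer_features(train, None, cfg)
        assert fs.n_features == 5
        assert none_fs is None

    def test_fused_hidden_mode_width(self, split, tiny_config):
        train, test = split
        cfg = tiny_config.with_(feature_mode="fused_hidden")
        tr_fs, te_fs, _ = generate_transfer_features(train, test, cfg)
        assert tr_fs.n_features == 5 + cfg.recurrent_units
        assert te_fs.provenance[5] == "gru_hidden:0"
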