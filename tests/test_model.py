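import numpy as np
import pandas as pd
import pytest

from cfcnv.model import (
    ModelConfig,
    TrainedModel,
    apportion,
    attention_weights,
    build_model,
    grid_search,
    predict,
    split_dataset,
    train,
)

SMALL = dict(conv1_filters=8, conv2_filters=8, attention_dim=8,
             dense1_units=16, dense2_units=8, learning_rate=3e-3,
             batch_size=64, seed=0)


def separable_data(n=200, m=500, seed=0):
    """One implanted high-effect region on a flat background."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(1.0, 0.05, size=(n, m))
    X[y == 1, 250:260] *= 1.6
    return X, y


@pytest.fixture(scope="module")
def separable_model():
    X, y = separable_data()
    cfg = ModelConfig(**SMALL, epochs=15)
    return train(X, y, cfg=cfg), X, y


class TestApportion:
    def test_exact_fractions(self):
        assert apportion(100) == (75, 5, 20)

    def test_cohort_4470(self):
        # floors (3352, 223, 894), remainders (.5, .5, 0), tie -> train
        assert apportion(4470) == (3353, 223, 894)

    def test_tie_broken_towards_train(self):
        # n=10: floors (7, 0, 2), remainders (.5, .5, 0) -> leftover to train
        assert apportion(10) == (8, 0, 2)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            apportion(10, (0.5, 0.2, 0.2))

    def test_partitions_disjoint_exhaustive_for_all_n(self):
        for n in range(3, 1001):
            sizes = apportion(n)
            assert sum(sizes) == n
            assert all(s >= 0 for s in sizes)


class TestSplitDataset:
    def test_membership_partitions_indices(self):
        spec = split_dataset(137, seed=3)
        combined = np.concatenate([spec.train_idx, spec.val_idx, spec.test_idx])
        assert sorted(combined) == list(range(137))
        assert spec.sizes == tuple(map(len, (spec.train_idx, spec.val_idx,
                                             spec.test_idx)))

    def test_deterministic(self):
        a = split_dataset(50, seed=1)
        b = split_dataset(50, seed=1)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_seed_changes_membership_not_sizes(self):
        a = split_dataset(50, seed=1)
        b = split_dataset(50, seed=2)
        assert a.sizes == b.sizes
        assert not np.array_equal(a.train_idx, b.train_idx)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2)


class TestBuildModel:
    def test_default_config_builds_at_genome_scale(self):
        net = build_model(ModelConfig(), 4520)
        prob = net.forward(np.zeros((2, 4520), dtype=np.float32))["prob"]
        assert prob.shape == (2,)
        assert net.n_parameters > 0

    def test_input_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(ModelConfig(), 5)

    def test_collapsing_config_rejected(self):
        cfg = ModelConfig(pool1=64, pool2=64)
        with pytest.raises(ValueError):
            build_model(cfg, 100)

    def test_bad_dropout_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout_rate=1.0)


class TestTrain:
    def test_separable_data_high_accuracy(self, separable_model):
        tm, X, y = separable_model
        acc = (predict(tm, X, return_labels=True) == y).mean()
        assert acc > 0.95

    def test_loss_decreases(self, separable_model):
        tm, _, _ = separable_model
        assert tm.history.train_loss.iloc[-1] <= tm.history.train_loss.iloc[0]

    def test_history_has_one_row_per_epoch(self, separable_model):
        tm, _, _ = separable_model
        assert len(tm.history) == tm.config.epochs
        assert list(tm.history.epoch) == list(range(1, tm.config.epochs + 1))

    def test_single_class_rejected(self):
        X = np.ones((10, 40))
        with pytest.raises(ValueError, match="single class"):
            train(X, np.ones(10, dtype=int), cfg=ModelConfig(**SMALL, epochs=1))

    def test_non_binary_labels_rejected(self):
        X = np.ones((10, 40))
        with pytest.raises(ValueError, match="0/1"):
            train(X, np.arange(10), cfg=ModelConfig(**SMALL, epochs=1))

    def test_validation_monitored(self):
        X, y = separable_data(n=80, m=100)
        cfg = ModelConfig(**SMALL, epochs=2)
        tm = train(X[:60], y[:60], X[60:], y[60:], cfg=cfg)
        assert "val_accuracy" in tm.history.columns

    def test_deterministic_for_fixed_seed(self):
        X, y = separable_data(n=60, m=80)
        cfg = ModelConfig(**SMALL, epochs=3)
        a = train(X, y, cfg=cfg)
        b = train(X, y, cfg=cfg)
        np.testing.assert_array_equal(predict(a, X), predict(b, X))


class TestPredict:
    def test_probabilities_in_unit_interval(self, separable_model):
        tm, X, _ = separable_model
        p = predict(tm, X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_exact_threshold_is_negative_class(self, separable_model):
        # strict "above threshold": p == 0.5 -> class 0
        tm, _, _ = separable_model
        p = np.array([0.5, 0.5 + 1e-9])
        assert ((p > tm.config.threshold).astype(int) == [0, 1]).all()

    def test_duplicate_rows_identical(self, separable_model):
        tm, X, _ = separable_model
        p = predict(tm, np.stack([X[0], X[0]]))
        assert p[0] == p[1]

    def test_shape_mismatch_rejected(self, separable_model):
        tm, _, _ = separable_model
        with pytest.raises(ValueError, match="expected shape"):
            predict(tm, np.zeros((2, 7)))


class TestAttentionWeights:
    def test_nonnegative_and_sums_to_one(self, separable_model):
        tm, X, _ = separable_model
        w = attention_weights(tm, X)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert len(w) == X.shape[1]

    def test_invariant_to_sample_order(self, separable_model):
        tm, X, _ = separable_model
        w1 = attention_weights(tm, X)
        w2 = attention_weights(tm, X[::-1])
        np.testing.assert_allclose(w1, w2, atol=1e-9)

    def test_implanted_region_upweighted(self, separable_model):
        tm, X, _ = separable_model
        w = attention_weights(tm, X)
        signal = w[250:260].mean()
        assert signal > w.mean()

    def test_singleton_pooled_length_uniform(self):
        rng = np.random.default_rng(0)
        # 16 windows -> pooled length 1 under this config
        cfg = ModelConfig(conv1_filters=4, conv1_kernel=4, pool1=13,
                          conv2_filters=4, conv2_kernel=1, pool2=1,
                          attention_dim=4, dense1_units=8, dense2_units=4,
                          learning_rate=1e-3, batch_size=8, epochs=2, seed=0)
        y = np.arange(20) % 2
        X = rng.normal(1.0, 0.1, size=(20, 16)) * (1 + 0.5 * y[:, None])
        tm = train(X, y, cfg=cfg)
        w = attention_weights(tm, X)
        np.testing.assert_allclose(w, 1.0 / 16, rtol=1e-6)

    def test_empty_reference_rejected(self, separable_model):
        tm, _, _ = separable_model
        with pytest.raises(ValueError, match="non-empty"):
            attention_weights(tm, np.zeros((0, tm.n_windows)))


class TestGridSearch:
    def test_single_config_identity(self):
        X, y = separable_data(n=60, m=80)
        base = ModelConfig(**SMALL, epochs=2)
        best, table = grid_search({"conv1_filters": [8]},
                                  X[:40], y[:40], X[40:], y[40:], base_cfg=base)
        assert best.conv1_filters == 8
        assert len(table) == 1

    def test_grid_cardinality(self):
        X, y = separable_data(n=60, m=80)
        base = ModelConfig(**SMALL, epochs=1)
        _, table = grid_search(
            {"conv1_filters": [4, 8], "dense1_units": [8, 16]},
            X[:40], y[:40], X[40:], y[40:], base_cfg=base,
        )
        assert len(table) == 4

    def test_planted_best_selected(self):
        X, y = separable_data(n=80, m=60)
        base = ModelConfig(**SMALL, epochs=3)
        # kernel 64 > n_windows cripples that grid point entirely
        best, table = grid_search(
            {"conv1_kernel": [8, 64]},
            X[:60], y[:60], X[60:], y[60:], base_cfg=base,
        )
        assert best.conv1_kernel == 8
        failed = table[table.conv1_kernel == 64]
        assert failed.val_auc.isna().all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            grid_search({}, None, None, None, None)


class TestSaveLoad:
    def test_roundtrip(self, separable_model, tmp_path):
        tm, X, _ = separable_model
        tm.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        np.testing.assert_allclose(predict(loaded, X[:5]), predict(tm, X[:5]),
                                   rtol=1e-6)
        assert loaded.config == tm.config
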