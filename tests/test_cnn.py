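import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semglite import (
    ModelConfig,
    TrainConfig,
    count_parameters,
    init_model,
    layer_shapes,
    predict_proba,
    predict_proba_batch,
    train_binary,
    load_model,
    save_model,
)
from semglite.cnn import _forward


def _random_valid_config(rng):
    """Random config whose conv/pool stages all keep length >= 1."""
    while True:
        cfg = dict(
            input_len=int(rng.integers(10, 200)),
            n_conv_layers=int(rng.integers(1, 3)),
            n_filters=int(rng.integers(1, 9)),
            kernel_len=int(rng.integers(2, 8)),
            stride=int(rng.integers(1, 3)),
            pool_len=int(rng.integers(2, 4)),
            fc_hidden=None if rng.random() < 0.7 else int(rng.integers(2, 30)),
        )
        try:
            layer_shapes(ModelConfig(**cfg))
            return ModelConfig(**cfg)
        except ValueError:
            continue


class TestLayerShapes:
    @pytest.mark.parametrize(
        "input_len, expected",
        [
            (250, [("input", 250, 1), ("conv1", 246, 7), ("pool1", 123, 7),
                   ("conv2", 119, 7), ("pool2", 59, 7), ("flatten", 413, 1),
                   ("output", 2, 1)]),
            (146, [("input", 146, 1), ("conv1", 142, 7), ("pool1", 71, 7),
                   ("conv2", 67, 7), ("pool2", 33, 7), ("flatten", 231, 1),
                   ("output", 2, 1)]),
        ],
    )
    def test_standard_topologies(self, input_len, expected):
        assert layer_shapes(ModelConfig(input_len=input_len)) == expected

    def test_degenerate_input_names_failing_layer(self):
        with pytest.raises(ValueError, match="conv2"):
            layer_shapes(ModelConfig(input_len=6, kernel_len=5, pool_len=2))

    def test_shapes_agree_with_forward_pass(self):
        """Executed forward passes on random inputs for 20 random configs."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            cfg = _random_valid_config(rng)
            model = init_model(cfg, seed=3)
            x = rng.standard_normal((2, cfg.input_len))
            probs, cache = _forward(model, x)
            shapes = dict((n, (l, c)) for n, l, c in layer_shapes(cfg))
            for j, conv_cache in enumerate(cache["conv"], start=1):
                assert conv_cache["z"].shape[2] == shapes[f"conv{j}"][0]
                assert conv_cache["z"].shape[1] == shapes[f"conv{j}"][1]
            assert cache["flat"].shape[1] == shapes["flatten"][0]
            assert probs.shape == (2, cfg.n_outputs)


class TestCountParameters:
    def test_first_conv_layer(self):
        # K_in=1, N=7, F=5 -> 7*(5+1) = 42
        cfg = ModelConfig(input_len=146)
        assert count_parameters(cfg) == 42 + 7 * (5 * 7 + 1) + (231 + 1) * 2

    def test_minimal_net(self):
        cfg = ModelConfig(input_len=1, n_conv_layers=1, n_filters=1,
                          kernel_len=1, pool_len=1, n_outputs=2)
        assert count_parameters(cfg) == 2 + 2 * 2

    def test_counts_match_actual_weight_sizes(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            cfg = _random_valid_config(rng)
            m = init_model(cfg, seed=0)
            n = sum(w.size + b.size for w, b in m.conv_weights)
            n += m.fc_weights[0].size + m.fc_weights[1].size
            if m.fc_hidden_weights is not None:
                n += m.fc_hidden_weights[0].size + m.fc_hidden_weights[1].size
            assert n == count_parameters(cfg)


class TestPredictProba:
    def test_probabilities_sum_to_one(self):
        cfg = ModelConfig(input_len=30)
        m = init_model(cfg, seed=5)
        p_task, p_other = predict_proba(m, np.random.default_rng(0).standard_normal(30))
        assert 0 <= p_task <= 1 and 0 <= p_other <= 1
        assert p_task + p_other == pytest.approx(1.0, abs=1e-6)

    def test_zero_weight_model_is_indifferent(self):
        m = init_model(ModelConfig(input_len=30), seed=0, zero=True)
        p_task, p_other = predict_proba(m, np.ones(30))
        assert p_task == pytest.approx(0.5) and p_other == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        m = init_model(ModelConfig(input_len=30), seed=0)
        with pytest.raises(ValueError, match="length"):
            predict_proba(m, np.zeros(29))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_softmax_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        m = init_model(ModelConfig(input_len=25, kernel_len=3), seed=seed % 997)
        X = 10.0 * rng.standard_normal((5, 25))
        p = predict_proba_batch(m, X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()


@pytest.fixture(scope="module")
def separable_set():
    """Two amplitude-separated noise classes, >=100 windows each."""
    rng = np.random.default_rng(21)
    n, L = 150, 60
    X0 = 0.5 * rng.standard_normal((n, L))
    X1 = 2.0 * rng.standard_normal((n, L))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    order = rng.permutation(len(y))
    return X[order], y[order]


class TestTrainBinary:
    def test_separable_data_reaches_high_training_accuracy(self, separable_set):
        X, y = separable_set
        m = train_binary(X[:240], y[:240], X[240:], y[240:],
                         ModelConfig(input_len=60),
                         TrainConfig(max_epochs=50, seed=4))
        assert m.train_history[-1]["train_acc"] >= 0.95
        # held-out task windows recovered with p_task > 0.5 at least 90% of the time
        task = X[240:][y[240:] == 1]
        p = predict_proba_batch(m, task)[:, 0]
        assert (p > 0.5).mean() >= 0.9

    def test_label_shuffled_data_is_chance_level(self, separable_set):
        X, y = separable_set
        m = train_binary(X[:240], y[:240], X[240:], y[240:],
                         ModelConfig(input_len=60),
                         TrainConfig(max_epochs=15, seed=4, shuffle_labels=True))
        assert m.train_history[-1]["val_acc"] == pytest.approx(0.5, abs=0.15)

    def test_zero_epochs_returns_untrained_model(self, separable_set):
        X, y = separable_set
        m = train_binary(X, y, None, None, ModelConfig(input_len=60),
                         TrainConfig(max_epochs=0, seed=0))
        assert m.train_history == []

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 20))
        with pytest.raises(ValueError, match="both classes"):
            train_binary(X, np.zeros(10, dtype=int), None, None,
                         ModelConfig(input_len=20), TrainConfig())

    def test_training_is_seeded_deterministic(self, separable_set):
        X, y = separable_set
        args = (X[:60], y[:60], None, None, ModelConfig(input_len=60),
                TrainConfig(max_epochs=2, seed=9))
        a, b = train_binary(*args), train_binary(*args)
        for (wa, ba), (wb, bb) in zip(a.conv_weights, b.conv_weights):
            assert np.array_equal(wa, wb) and np.array_equal(ba, bb)
        assert np.array_equal(a.fc_weights[0], b.fc_weights[0])

    def test_inference_deterministic_despite_dropout_training(self, separable_set):
        X, y = separable_set
        m = train_binary(X[:60], y[:60], None, None, ModelConfig(input_len=60),
                         TrainConfig(max_epochs=2, seed=9))
        p1 = predict_proba_batch(m, X[60:80])
        p2 = predict_proba_batch(m, X[60:80])
        assert np.array_equal(p1, p2)


def test_model_save_load_roundtrip(tmp_path, separable_set):
    X, y = separable_set
    m = train_binary(X[:60], y[:60], None, None, ModelConfig(input_len=60),
                     TrainConfig(max_epochs=1, seed=2), task_id=3)
    path = save_model(m, tmp_path / "task3.npz")
    back = load_model(path)
    assert back.task_id == 3
    assert back.config == m.config
    assert np.array_equal(back.fc_weights[0], m.fc_weights[0])
    assert np.array_equal(predict_proba_batch(back, X[:5]),
                          predict_proba_batch(m, X[:5]))
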