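"""Tests of the CNN-GRU architecture, its gradients and the training protocol."""

import numpy as np
import pytest

from pcgnet import nn
from pcgnet.classifier import (ModelSpec, ShapeError, TrainConfig,
                               build_baseline, build_cnn_gru, compile_model,
                               encode_labels, output_shapes, predict, train)

TABLE_SHAPES = [(982, 9), (245, 9), (226, 9), (56, 9), (37, 9), (9, 9),
                (128,), (2,)]


def separable_frames(n_per_class=80, length=1001, seed=0):
    """Two classes of noisy frames differing in a strong periodic component."""
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    X = 0.5 * rng.standard_normal((2 * n_per_class, length)).astype(np.float32)
    X[:n_per_class] += np.sin(2 * np.pi * t / 100)[None, :]
    X[n_per_class:] += np.sin(2 * np.pi * t / 60)[None, :]
    y = np.array([0] * n_per_class + [1] * n_per_class)
    order = rng.permutation(2 * n_per_class)
    return X[order], y[order]


class TestArchitecture:
    def test_default_stack_structure(self):
        spec = build_cnn_gru()
        kinds = [l.kind for l in spec.layers]
        assert kinds == ["conv1d", "maxpool1d"] * 3 + ["gru", "dense"]
        assert spec.layers[-1].activation == "softmax"
        assert spec.layers[-1].units == 2
        assert spec.layers[-2].units == 128 and spec.layers[-2].dropout == 0.5

    def test_default_output_shapes(self):
        assert output_shapes(build_cnn_gru()) == TABLE_SHAPES

    def test_four_layer_variant_order(self):
        spec = build_cnn_gru(kernel=10, n_layers=4)
        assert [l.kind for l in spec.layers] == ["conv1d", "maxpool1d", "gru",
                                                 "dense"]

    @pytest.mark.parametrize("kernel", [10, 20, 30])
    @pytest.mark.parametrize("n_layers", [4, 6, 8])
    def test_ablation_grid_builds(self, kernel, n_layers):
        spec = build_cnn_gru(kernel=kernel, n_layers=n_layers)
        assert output_shapes(spec)[-1] == (2,)

    @pytest.mark.parametrize("units", [8, 16, 32, 64, 128, 256])
    def test_unit_sweep_builds(self, units):
        spec = build_cnn_gru(gru_units=units)
        assert output_shapes(spec)[-2] == (units,)

    def test_conv_boundary_length_one(self):
        from pcgnet.classifier import LayerSpec

        spec = ModelSpec(layers=[LayerSpec(kind="conv1d", size=20, filters=9,
                                           activation="relu")], input_len=20)
        assert output_shapes(spec) == [(1, 9)]

    def test_too_short_input_fails_shape_propagation(self):
        with pytest.raises(ShapeError):
            build_cnn_gru(input_len=50)

    def test_baselines(self):
        cnn = build_baseline("cnn")
        assert all(l.kind != "gru" for l in cnn.layers)
        gru = build_baseline("gru", units=128)
        assert sum(l.kind == "gru" for l in gru.layers) == 1
        for spec in (cnn, gru):
            assert spec.input_len == 1001 and output_shapes(spec)[-1] == (2,)
        with pytest.raises(ValueError):
            build_baseline("mlp")

    def test_spec_json_round_trip(self):
        spec = build_cnn_gru()
        back = ModelSpec.from_json(spec.to_json())
        assert back == spec

    def test_forward_shapes_match_declared(self):
        spec = build_cnn_gru()
        model = compile_model(spec, seed=0)
        x = np.zeros((3, 1001, 1), dtype=np.float32)
        for layer, expected in zip(model.layers, output_shapes(spec)):
            x = layer.forward(x)
            assert x.shape[1:] == tuple(expected)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        model = nn.Model([
            nn.Conv1D(1, 2, 5, rng=rng, dtype=np.float64),
            nn.MaxPool1D(2),
            nn.Conv1D(2, 3, 4, rng=rng, dtype=np.float64),
            nn.MaxPool1D(3),
            nn.GRU(3, 4, dropout=0.0, rng=rng, dtype=np.float64),
            nn.Dense(4, 2, rng=rng, dtype=np.float64),
        ], l2=0.01)
        X = rng.standard_normal((5, 40, 1))
        y = rng.integers(0, 2, 5)

        def loss():
            logits = model.forward(X, train=False)
            p = nn.softmax(logits)
            ce = -np.mean(np.log(p[np.arange(5), y]))
            reg = sum(np.sum(v ** 2) for l in model.layers
                      for k, v in l.params.items() if k[0] in "WU")
            return ce + 0.5 * model.l2 * reg

        model.loss_and_grad(X, y, train=False)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for layer in model.layers:
            for k, p in layer.params.items():
                flat = p.reshape(-1)
                for idx in check_rng.choice(flat.size, size=min(4, flat.size),
                                            replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss()
                    flat[idx] = orig - eps
                    lm = loss()
                    flat[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    analytic = layer.grads[k].reshape(-1)[idx]
                    assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-8)


class TestTraining:
    def test_learns_separable_frames(self):
        X, y = separable_frames()
        spec = build_cnn_gru()
        cfg = TrainConfig(seed=1)
        model, hist = train(spec, X[:120], y[:120], X[120:], y[120:], cfg)
        assert len(hist["train_loss"]) <= 50
        assert hist["train_acc"][-1] >= 0.95

    def test_loss_decreases_early(self):
        X, y = separable_frames(seed=5)
        spec = build_cnn_gru()
        cfg = TrainConfig(seed=2, max_epochs=8, patience=8)
        _, hist = train(spec, X[:120], y[:120], X[120:], y[120:], cfg)
        losses = hist["train_loss"]
        assert losses[-1] < losses[0]

    def test_early_stopping_with_frozen_weights(self):
        # zero learning rate freezes the validation loss, so training must
        # halt after exactly 1 + patience epochs
        X, y = separable_frames(n_per_class=20)
        spec = build_cnn_gru()
        cfg = TrainConfig(seed=3, lr=0.0, patience=10, max_epochs=50)
        _, hist = train(spec, X[:30], y[:30], X[30:], y[30:], cfg)
        assert len(hist["val_loss"]) == 11
        assert np.ptp(hist["val_loss"]) == 0.0

    def test_epochs_never_exceed_maximum(self):
        X, y = separable_frames(n_per_class=20)
        cfg = TrainConfig(seed=4, max_epochs=5, patience=5)
        _, hist = train(build_cnn_gru(), X[:30], y[:30], X[30:], y[30:], cfg)
        assert len(hist["train_loss"]) <= 5
        assert all(len(v) == len(hist["train_loss"]) for v in hist.values())

    def test_deterministic_given_seed(self):
        X, y = separable_frames(n_per_class=20)
        cfg = TrainConfig(seed=5, max_epochs=3, patience=3)
        _, h1 = train(build_cnn_gru(), X[:30], y[:30], X[30:], y[30:], cfg)
        _, h2 = train(build_cnn_gru(), X[:30], y[:30], X[30:], y[30:], cfg)
        assert h1 == h2

    def test_degenerate_splits_rejected(self):
        X, y = separable_frames(n_per_class=10)
        cfg = TrainConfig(seed=0, max_epochs=2, patience=2)
        with pytest.raises(ValueError, match="empty"):
            train(build_cnn_gru(), X[:0], y[:0], X, y, cfg)
        ones = np.ones(len(y), dtype=int)
        with pytest.raises(ValueError, match="single class"):
            train(build_cnn_gru(), X, ones, X, y, cfg)


@pytest.fixture(scope="module")
def model():
    return compile_model(build_cnn_gru(), seed=0)


class TestPredict:

    def test_probabilities_sum_to_one(self, model, rng):
        X = rng.standard_normal((7, 1001)).astype(np.float32)
        probs, labels = predict(model, X, 1001)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))

    def test_duplicated_frame_identical_output(self, model, rng):
        x = rng.standard_normal(1001).astype(np.float32)
        probs, _ = predict(model, np.stack([x, x]), 1001)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_all_zero_frame_accepted(self, model):
        probs, labels = predict(model, np.zeros((1, 1001)), 1001)
        assert probs.shape == (1, 2) and labels.shape == (1,)

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="length"):
            predict(model, np.zeros((1, 500)), 1001)


class TestLabels:
    def test_sudden_death_is_positive_class(self):
        enc = encode_labels(np.array(["survival", "sudden_death"]))
        np.testing.assert_array_equal(enc, [0, 1])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            encode_labels(np.array(["healthy"]))
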