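"""The per-timestep recurrent classifier: architecture, training, prediction."""

import numpy as np
import pytest

from capscan.dataset import class_weights
from capscan.nn import (
    HyperParams,
    SequenceClassifier,
    build_model,
    predict_proba,
    train_model,
)

from .conftest import imbalanced_sequences, separable_sequences

SMALL_HP = dict(n_recurrent_layers=1, units_per_layer=64, dropout=0.2, dense_units=32, batch_size=32)


class TestArchitecture:
    def test_reference_config_layer_stack(self):
        hp = HyperParams(n_recurrent_layers=2, units_per_layer=128, dense_units=64)
        spec = build_model(hp, steps=10, n_features=5, n_classes=4)
        assert len(spec.layers) == 7  # lstm,bn,drop x2 + relu dense
        assert spec.layers[0] == ("lstm", 128)
        assert spec.layers[3] == ("lstm", 64)  # halved width
        assert spec.layers[6][:2] == ("dense", 64)

    def test_single_layer_config(self):
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        assert sum(1 for d in spec.layers if d[0] == "lstm") == 1

    def test_width_floor_at_32(self):
        hp = HyperParams(n_recurrent_layers=3, units_per_layer=64)
        spec = build_model(hp, 10, 4, 2)
        widths = [d[1] for d in spec.layers if d[0] == "lstm"]
        assert widths == [64, 32, 32]

    @pytest.mark.parametrize("field, value", [("n_recurrent_layers", 4), ("dropout", 0.7), ("units_per_layer", 16)])
    def test_out_of_range_hyperparams_rejected(self, field, value):
        with pytest.raises(ValueError):
            HyperParams(**{**SMALL_HP, field: value})

    def test_untrained_softmax_rows_sum_to_one(self, rng):
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 3)
        model = SequenceClassifier(spec, seed=0)
        probs = model.predict_proba(rng.standard_normal((6, 10, 4)))
        assert probs.shape == (6, 10, 3)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Finite-difference check of the full backward pass on a tiny model."""
        from capscan.nn import _softmax, _weighted_loss

        rng = np.random.default_rng(0)
        spec = build_model(HyperParams(**SMALL_HP), steps=3, n_features=2, n_classes=2)
        # shrink by hand for speed: the check is structural, not scale-dependent
        spec.layers = [("lstm", 4), ("batchnorm",), ("dense", 3, "relu")]
        model = SequenceClassifier(spec, seed=1)
        x = rng.standard_normal((4, 3, 2))
        y = rng.integers(0, 2, (4, 3))
        mask = np.zeros((4, 3), dtype=bool)
        w = np.ones(2)

        def loss_value():
            logits, _, _ = model._forward(x, training=True, rng=None)
            return _weighted_loss(_softmax(logits), y, mask, w)[0]

        logits, caches, head_cache = model._forward(x, training=True, rng=None)
        _, dlogits = _weighted_loss(_softmax(logits), y, mask, w)
        grads = model._backward(dlogits, caches, head_cache)
        params = model.parameters()
        eps = 1e-6
        for p, g in zip(params, grads):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up = loss_value()
            p[idx] = orig - eps
            down = loss_value()
            p[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert abs(numeric - g[idx]) < 1e-4 * max(1.0, abs(numeric))


class TestTraining:
    def test_separable_task_reaches_95_percent(self):
        data = separable_sequences(seed=0)
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        model, history = train_model(spec, data, epochs=50, seed=3)
        acc = float((model.predict_proba(data.inputs).argmax(-1) == data.targets).mean())
        assert acc >= 0.95
        assert len(history["loss"]) <= 50

    def test_loss_decreases_over_first_five_epochs(self):
        data = separable_sequences(seed=1)
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        _, history = train_model(spec, data, epochs=5, seed=4)
        assert history["loss"][-1] < history["loss"][0]

    def test_fixed_seed_reproduces_history(self):
        data = separable_sequences(seed=2)
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        _, h1 = train_model(spec, data, epochs=8, seed=5)
        _, h2 = train_model(spec, data, epochs=8, seed=5)
        assert h1["loss"] == h2["loss"]

    def test_learning_rate_reduced_after_plateau(self):
        # constant labels on noise: no learnable signal, so validation loss
        # plateaus and the schedule must cut the learning rate below 0.001
        rng = np.random.default_rng(0)
        data = separable_sequences(seed=3)
        data.inputs = rng.standard_normal(data.inputs.shape)
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        _, history = train_model(spec, data, epochs=30, seed=6)
        assert history["lr"][-1] < 0.001

    def test_class_weighting_improves_minority_recall(self):
        wins = 0
        for rep in range(3):
            data = imbalanced_sequences(seed=rep)
            spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
            recalls = {}
            for name, w in [("unweighted", None), ("weighted", class_weights(dataset=data))]:
                model, _ = train_model(spec, data, weights=w, epochs=30, seed=100 + rep)
                pred = model.predict_proba(data.inputs).argmax(-1)
                minority = data.targets == 1
                recalls[name] = float((pred[minority] == 1).mean())
            wins += recalls["weighted"] > recalls["unweighted"]
        assert wins == 3


class TestPrediction:
    def test_probability_simplex(self, rng):
        data = separable_sequences(seed=4, n_seq=8)
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        model, _ = train_model(spec, data, epochs=3, seed=7)
        probs = predict_proba(model, data.inputs)
        assert (probs >= 0).all() and np.allclose(probs.sum(-1), 1.0, atol=1e-9)

    def test_duplicated_inputs_identical_outputs(self):
        data = separable_sequences(seed=5, n_seq=6)
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        model, _ = train_model(spec, data, epochs=3, seed=8)
        doubled = np.concatenate([data.inputs, data.inputs])
        probs = model.predict_proba(doubled)
        assert np.array_equal(probs[: len(data.inputs)], probs[len(data.inputs) :])

    def test_shape_mismatch_raises(self):
        spec = build_model(HyperParams(**SMALL_HP), 10, 4, 2)
        model = SequenceClassifier(spec, seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 10, 7)))
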