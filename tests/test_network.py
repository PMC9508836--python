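"""CNN classifier: architecture, gradients, schedule, search, prediction."""

import numpy as np
import pytest

from denovotrio import nn, network
from denovotrio.network import (
    ClassificationResult,
    ModelConfig,
    SearchSpace,
    TrainingConfig,
    build_network,
    hyperparameter_search,
    learning_rate_at,
    load_checkpoint,
    save_checkpoint,
    se_block,
    train,
)

# tiny geometry: the layers are size-agnostic, so architecture and training
# mechanics are exercised on small images for speed
TINY = ModelConfig(conv_layers=3, filters_per_layer=4, se_block_every=3,
                   input_shape=(8, 8, 3))


def tiny_data(n=16, seed=0, size=8):
    """Separable toy set: positive images carry a bright column."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 40, size=(n, size, size, 3)).astype(np.uint8)
    y = (np.arange(n) % 2).astype(np.float32)
    x[y == 1, :, 2, :] = 255
    return x, y


class TestArchitecture:
    def test_forward_shape_and_probability_range(self):
        model = build_network(TINY, seed=0)
        x = np.random.default_rng(1).random((5, 8, 8, 3)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (5,)
        assert np.all((p >= 0) & (p <= 1)) and np.all(np.isfinite(p))

    def test_default_config_matches_published_topology(self):
        config = ModelConfig()
        assert config.conv_layers == 9
        assert config.filters_per_layer == 96
        assert config.se_block_every == 3
        model = build_network(config, seed=0)
        n_se = sum(isinstance(l, nn.SqueezeExcite) for l in model.layers)
        n_conv = sum(isinstance(l, nn.Conv2d) for l in model.layers)
        n_bn = sum(isinstance(l, nn.BatchNorm) for l in model.layers)
        assert (n_conv, n_bn, n_se) == (9, 3, 3)
        # head: pooling concat then a single-unit dense layer
        assert isinstance(model.layers[-2], nn.GlobalPoolConcat)
        assert model.layers[-1].w.value.shape == (2 * 96, 1)

    def test_se_block_count_follows_config(self):
        model = build_network(TINY, seed=0)
        assert sum(isinstance(l, nn.SqueezeExcite) for l in model.layers) == 1

    def test_indivisible_layer_count_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_layers=8, se_block_every=3)

    def test_same_seed_identical_initial_weights(self):
        a = build_network(TINY, seed=3).get_weights()
        b = build_network(TINY, seed=3).get_weights()
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_gradient_check(self):
        """Numeric finite-difference check of the full backward pass."""
        model = build_network(ModelConfig(conv_layers=3, filters_per_layer=2,
                                          se_block_every=3,
                                          input_shape=(5, 5, 3),
                                          l1_coefficient=0.0), seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((4, 5, 5, 3)).astype(np.float32)
        y = np.array([0, 1, 1, 0], dtype=np.float32)

        def loss_value():
            logits = model.forward(x.astype(np.float32), train=True)
            loss, _ = nn.bce_loss_and_grad(logits, y)
            return loss

        model.zero_grad()
        logits = model.forward(x, train=True)
        _, dlogits = nn.bce_loss_and_grad(logits, y)
        model.backward(dlogits)
        eps = 1e-3
        checked = 0
        for p in model.params():
            flat = p.value.reshape(-1)
            grad = p.grad.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, abs=2e-2)
                checked += 1
        assert checked > 10


class TestSeBlock:
    def test_output_shape_equals_input_shape(self):
        for shape in [(2, 4, 4, 8), (1, 3, 7, 16)]:
            x = np.random.default_rng(0).random(shape).astype(np.float32)
            assert se_block(x, reduction_ratio=4).shape == shape

    def test_zero_input_zero_output(self):
        x = np.zeros((2, 4, 4, 8), np.float32)
        assert not se_block(x).any()

    def test_gates_forced_open_gives_identity(self):
        rng = np.random.default_rng(0)
        layer = nn.SqueezeExcite(8, 4, rng)
        layer.w2.value[...] = 0.0
        layer.b2.value[...] = 50.0  # sigmoid saturates at 1
        x = rng.random((2, 4, 4, 8)).astype(np.float32)
        assert np.allclose(se_block(x, layer=layer), x, atol=1e-6)

    def test_bottleneck_floors_at_one_unit(self):
        layer = nn.SqueezeExcite(4, 16, np.random.default_rng(0))
        assert layer.w1.value.shape == (4, 1)


class TestSchedule:
    def test_stepwise_decay_values(self):
        config = TrainingConfig(initial_learning_rate=1e-3)
        assert learning_rate_at(0, config) == 1e-3
        assert learning_rate_at(9, config) == 1e-3
        assert learning_rate_at(10, config) == 5e-4
        assert learning_rate_at(25, config) == pytest.approx(2.5e-4)

    def test_early_stop_patience_arithmetic(self):
        """No improvement after the first epoch -> stop after patience more."""
        x, y = tiny_data(8, seed=0)
        # validation labels inverted: val loss can only get worse
        xv, yv = x.copy(), 1.0 - y
        config = TrainingConfig(max_epochs=30, early_stop_patience=5,
                                initial_learning_rate=0.05, batch_size=8,
                                rng_seed=0)
        model = build_network(TINY, seed=0)
        _, history = train(model, (x, y), (xv, yv), config)
        assert history.stopped_epoch == history.best_epoch + 5
        assert len(history.epochs) == history.stopped_epoch + 1

    def test_history_records_lr_schedule(self):
        x, y = tiny_data(8)
        config = TrainingConfig(max_epochs=12, early_stop_patience=11,
                                batch_size=8, rng_seed=0)
        model = build_network(TINY, seed=0)
        _, history = train(model, (x, y), (x, y), config)
        lrs = [e["lr"] for e in history.epochs]
        assert lrs[:10] == [config.initial_learning_rate] * 10
        assert lrs[10:12] == [config.initial_learning_rate * 0.5] * 2

    def test_best_epoch_checkpoint_restored(self):
        x, y = tiny_data(16, seed=1)
        config = TrainingConfig(max_epochs=15, early_stop_patience=14,
                                initial_learning_rate=0.02, batch_size=8,
                                rng_seed=1)
        model = build_network(TINY, seed=1)
        model, history = train(model, (x, y), (x, y), config)
        best = min(range(len(history.epochs)),
                   key=lambda i: history.epochs[i]["val_loss"])
        assert history.best_epoch == best
        loss, _ = network.evaluate_model(model, x, y)
        assert loss == pytest.approx(history.epochs[best]["val_loss"], rel=1e-5)

    def test_empty_dataset_rejected(self):
        model = build_network(TINY, seed=0)
        empty = (np.zeros((0, 8, 8, 3), np.uint8), np.zeros(0, np.float32))
        with pytest.raises(ValueError):
            train(model, empty, empty, TrainingConfig())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(max_epochs=10, early_stop_patience=10)
        with pytest.raises(ValueError):
            TrainingConfig(initial_learning_rate=0.0)


class TestTrainingBehaviour:
    def test_overfits_tiny_memorizable_set(self):
        """Loss on 10 images approaches zero well within 200 epochs."""
        x, y = tiny_data(10, seed=2)
        config = TrainingConfig(max_epochs=200, early_stop_patience=199,
                                initial_learning_rate=0.05, batch_size=5,
                                rng_seed=2)
        model = build_network(TINY, seed=2)
        model, history = train(model, (x, y), (x, y), config)
        assert min(e["val_loss"] for e in history.epochs) < 0.05
        _, acc = network.evaluate_model(model, x, y)
        assert acc == 1.0

    def test_training_deterministic_under_seed(self):
        x, y = tiny_data(8)
        config = TrainingConfig(max_epochs=3, early_stop_patience=2,
                                batch_size=8, rng_seed=5)
        runs = []
        for _ in range(2):
            model = build_network(TINY, seed=5)
            _, history = train(model, (x, y), (x, y), config)
            runs.append([e["train_loss"] for e in history.epochs])
        assert runs[0] == runs[1]

    def test_warm_start_from_other_model_weights(self):
        sub = build_network(TINY, seed=0)
        x, y = tiny_data(8)
        config = TrainingConfig(max_epochs=2, early_stop_patience=1,
                                batch_size=8, optimizer="adamw",
                                weight_decay=1e-4,
                                init_weights=sub.get_weights())
        indel = build_network(TINY, seed=99)
        indel, _ = train(indel, (x, y), (x, y), config)
        assert indel is not None  # weights loaded without shape errors


class TestSearch:
    def test_samples_respect_bounds(self):
        space = SearchSpace()
        rng = np.random.default_rng(0)
        for _ in range(100):
            mcfg, tcfg = space.sample(rng, base_model=TINY)
            assert mcfg.filters_per_layer in space.filters
            assert tcfg.batch_size in space.batch_sizes
            assert space.l1_bounds[0] <= mcfg.l1_coefficient <= space.l1_bounds[1]
            assert (space.learning_rate_bounds[0] <=
                    tcfg.initial_learning_rate <= space.learning_rate_bounds[1])
            assert (space.weight_decay_bounds[0] <=
                    tcfg.weight_decay <= space.weight_decay_bounds[1])

    def test_log_sampling_median(self):
        """~half the learning-rate draws fall below the geometric midpoint."""
        space = SearchSpace()
        rng = np.random.default_rng(1)
        midpoint = np.sqrt(1e-8 * 0.01)  # 3.16e-5
        draws = [space.sample(rng)[1].initial_learning_rate
                 for _ in range(1000)]
        below = sum(d < midpoint for d in draws)
        assert 450 <= below <= 550

    def test_budget_one_returns_single_config(self):
        x, y = tiny_data(8)
        space = SearchSpace(filters=(4,), batch_sizes=(8,))
        base_t = TrainingConfig(max_epochs=2, early_stop_patience=1, batch_size=8)
        mcfg, tcfg, loss = hyperparameter_search(
            space, budget=1, train_set=(x, y), val_set=(x, y), seed=0,
            base_model=TINY, base_training=base_t)
        assert mcfg.filters_per_layer == 4
        assert np.isfinite(loss)

    def test_empty_budget_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search(SearchSpace(), 0, None, None)


class TestPredict:
    def test_threshold_inclusive_at_half(self):
        assert ClassificationResult(None, 0.5, "substitution").label == "DNM"
        assert ClassificationResult(None, 0.49, "substitution").label == "IV"
        assert ClassificationResult(None, 0.51, "substitution").label == "DNM"

    def test_missing_model_for_type_raises(self, denovo_site):
        from denovotrio.encoder import encode_trio
        image = encode_trio(denovo_site.window(), variant_type="insertion")
        with pytest.raises(KeyError, match="insertion"):
            network.predict({"substitution": build_network(TINY, 0)}, image)

    def test_prediction_deterministic(self, denovo_site):
        from denovotrio.encoder import encode_trio
        image = encode_trio(denovo_site.window(), variant_type="substitution")
        model = build_network(ModelConfig(conv_layers=3, filters_per_layer=4,
                                          se_block_every=3), seed=0)
        p1 = network.predict_proba(model, image)
        p2 = network.predict_proba(model, image)
        assert p1 == p2


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        model = build_network(TINY, seed=4)
        save_checkpoint(model, TINY, tmp_path / "sub.npz")
        loaded, config = load_checkpoint(tmp_path / "sub.npz")
        assert config == TINY
        x = np.random.default_rng(0).random((3, 8, 8, 3)).astype(np.float32)
        assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))
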