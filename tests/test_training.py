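import math

import numpy as np
import pytest

from hostdeplete.errors import ConfigError
from hostdeplete.model import ModelConfig, build_model
from hostdeplete.synthetic_data import host_profile, microbe_profile, _sample_chains
from hostdeplete.training import (
    LabeledDataset,
    TrainingConfig,
    bce_with_logits,
    loss,
    loss_and_grads,
    make_length_variants,
    train,
    validation_loss,
    write_history,
)

SMALL = ModelConfig(
    num_conv_layers=2, filters_per_layer=4, kernel_length=5, pool_length=2, min_input_length=10
)


def _small_dataset(n=60, length=100, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    host = _sample_chains(host_profile(), [length] * half, rng)
    microbe = _sample_chains(microbe_profile(), [length] * (n - half), rng)
    return LabeledDataset([(b, 1) for b in host] + [(b, 0) for b in microbe])


class TestMakeLengthVariants:
    def test_one_crop_per_supported_length(self):
        ds = LabeledDataset([("A" * 10000, 1)])
        out = make_length_variants(ds, (100, 1000, 10000), seed=0)
        assert sorted(len(b) for b, _ in out.reads) == [100, 1000, 10000]
        assert all(label == 1 for _, label in out.reads)

    def test_short_read_contributes_only_short_variants(self):
        ds = LabeledDataset([("C" * 500, 0)])
        out = make_length_variants(ds, (100, 1000, 10000), seed=0)
        assert [len(b) for b, _ in out.reads] == [100]

    def test_seeded_crop_positions_reproducible(self):
        ds = LabeledDataset([("ACGT" * 2500, 1)])
        a = make_length_variants(ds, (100, 1000), seed=3)
        b = make_length_variants(ds, (100, 1000), seed=3)
        assert a.reads == b.reads

    def test_crops_are_substrings(self):
        bases = _sample_chains(microbe_profile(), [2000], np.random.default_rng(1))[0]
        out = make_length_variants(LabeledDataset([(bases, 0)]), (100, 1000), seed=5)
        for crop, _ in out.reads:
            assert crop in bases


class TestLoss:
    def test_zero_weight_balanced_is_ln2(self):
        model = build_model(SMALL, seed=0).set_all_zero()
        batch = np.random.default_rng(0).random((4, 20, 4)).astype(np.float32)
        value = loss(model, batch, [0, 1, 0, 1], TrainingConfig())
        assert value == pytest.approx(math.log(2), abs=1e-9)

    def test_no_regularization_equals_plain_bce(self):
        model = build_model(SMALL, seed=1)
        batch = np.random.default_rng(1).random((4, 20, 4)).astype(np.float32)
        labels = [1, 0, 1, 1]
        config = TrainingConfig(l2_lambda=0.0, input_grad_lambda=0.0)
        logits = model.logits(batch)
        assert loss(model, batch, labels, config) == pytest.approx(
            bce_with_logits(logits, np.array(labels)), abs=1e-12
        )

    def test_two_read_toy_matches_independent_arithmetic(self):
        """BCE via math.log, L2 via direct sums, input-gradient penalty via
        finite differences of the logit with respect to the input."""
        config = ModelConfig(
            num_conv_layers=1, filters_per_layer=2, kernel_length=3,
            pool_length=2, min_input_length=4,
        )
        model = build_model(config, seed=9)
        for name in model.params:
            model.params[name] = model.params[name].astype(np.float64)
        rng = np.random.default_rng(7)
        batch = rng.random((2, 8, 4))
        labels = [1, 0]
        tc = TrainingConfig(l2_lambda=0.01, input_grad_lambda=0.5)

        logits = model.logits(batch)
        probs = 1.0 / (1.0 + np.exp(-logits))
        bce = -(math.log(probs[0]) + math.log(1.0 - probs[1])) / 2.0
        l2 = sum(
            float((p**2).sum())
            for n, p in model.params.items()
            if not n.endswith("_b")
        )
        eps = 1e-6
        grad_sq = 0.0
        for n in range(2):
            for t in range(8):
                for c in range(4):
                    plus = batch.copy()
                    plus[n, t, c] += eps
                    minus = batch.copy()
                    minus[n, t, c] -= eps
                    d = (model.logits(plus)[n] - model.logits(minus)[n]) / (2 * eps)
                    grad_sq += d * d
        expected = bce + 0.01 * l2 + 0.5 * grad_sq / 2.0
        assert loss(model, batch, labels, tc) == pytest.approx(expected, rel=1e-5)

    def test_misaligned_batch_raises(self):
        model = build_model(SMALL, seed=0)
        batch = np.zeros((3, 20, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            loss(model, batch, [1, 0], TrainingConfig())

    def test_regularization_monotonicity(self):
        model = build_model(SMALL, seed=2)
        batch = np.random.default_rng(2).random((4, 20, 4)).astype(np.float32)
        labels = [1, 0, 0, 1]
        values = [
            loss(model, batch, labels, TrainingConfig(l2_lambda=lam, input_grad_lambda=ig))
            for lam, ig in [(0.0, 0.0), (1e-4, 0.0), (1e-2, 0.0), (1e-2, 1e-2), (1e-2, 1.0)]
        ]
        assert values == sorted(values)


class TestGradients:
    def test_full_loss_gradient_matches_finite_differences(self):
        config = ModelConfig(
            num_conv_layers=2, filters_per_layer=3, kernel_length=3,
            pool_length=2, min_input_length=4,
        )
        model = build_model(config, seed=3)
        for name in model.params:
            model.params[name] = model.params[name].astype(np.float64)
        rng = np.random.default_rng(0)
        batch = rng.random((3, 11, 4))
        labels = [1, 0, 1]
        tc = TrainingConfig(l2_lambda=1e-3, input_grad_lambda=0.5)
        _, grads = loss_and_grads(model, batch, labels, tc)
        eps = 1e-6
        for name, param in model.params.items():
            flat = np.atleast_1d(param).reshape(-1)
            grad = np.atleast_1d(grads[name]).reshape(-1)
            idxs = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss(model, batch, labels, tc)
                flat[i] = orig - eps
                down = loss(model, batch, labels, tc)
                flat[i] = orig
                fd = (up - down) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7), name


class TestTrain:
    def test_empty_dataset_rejected(self):
        model = build_model(SMALL, seed=0)
        with pytest.raises(ConfigError):
            train(model, LabeledDataset([]), _small_dataset(10), TrainingConfig())

    def test_single_class_rejected(self):
        model = build_model(SMALL, seed=0)
        one_class = LabeledDataset([("ACGT" * 30, 1)] * 4)
        with pytest.raises(ConfigError):
            train(model, one_class, _small_dataset(10), TrainingConfig())

    def test_patience_zero_stops_at_first_plateau(self):
        model = build_model(SMALL, seed=0)
        data = _small_dataset(20, seed=1)
        config = TrainingConfig(patience=0, max_epochs=50, seed=0, batch_size=10,
                                learning_rate=10.0)  # destructive lr forces a plateau
        _, history = train(model, data, data, config)
        assert len(history) < 50
        val = [h["val_loss"] for h in history]
        # stopped exactly at the first epoch that failed to improve
        for i in range(len(history) - 1):
            assert val[i] == min(val[: i + 1])
        assert val[-1] >= min(val)

    def test_best_epoch_weights_restored(self):
        model = build_model(SMALL, seed=4)
        data = _small_dataset(30, seed=2)
        config = TrainingConfig(patience=1, max_epochs=6, seed=4, batch_size=10)
        model, history = train(model, data, data, config)
        assert len(history) >= 1
        best = min(h["val_loss"] for h in history)
        assert validation_loss(model, data) == pytest.approx(best, abs=1e-9)

    def test_seed_determinism(self):
        data = _small_dataset(30, seed=3)
        config = TrainingConfig(max_epochs=2, seed=8, batch_size=10)
        m1, h1 = train(build_model(SMALL, seed=8), data, data, config)
        m2, h2 = train(build_model(SMALL, seed=8), data, data, config)
        assert h1 == h2
        for name in m1.params:
            np.testing.assert_array_equal(m1.params[name], m2.params[name])

    def test_learning_signal_on_separable_data(self):
        data = _small_dataset(60, seed=5)
        config = TrainingConfig(max_epochs=5, seed=1, batch_size=12)
        model, history = train(build_model(SMALL, seed=1), data, data, config)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_history_written_as_csv(self, tmp_path):
        path = tmp_path / "history.csv"
        write_history(
            [{"epoch": 1, "train_loss": 0.5, "val_loss": 0.4}], path
        )
        lines = path.read_text().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss"
        assert lines[1] == "1,0.5,0.4"
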