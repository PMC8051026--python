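"""Initialization, optimization contracts, early stopping, branch isolation."""

import numpy as np
import pytest

from plinet.layers import Dense
from plinet.model import ModelConfig, PLIModel
from plinet.objectives import LabeledBatch
from plinet.training import (
    Adam,
    TrainConfig,
    init_parameters,
    train_multi_task,
    train_single_task,
)

from conftest import TINY_MODEL_CONFIG, random_onehot


class TestInitParameters:
    def test_seeded_reproducibility(self, tiny_model):
        a = init_parameters(tiny_model, 7)
        b = init_parameters(tiny_model, 7)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_biases_zero_weights_bounded(self, tiny_model, tiny_params):
        for name, (shape, fi, fo) in tiny_model.param_specs().items():
            if fi == 0 and fo == 0:
                assert np.all(tiny_params[name] == 0)
            else:
                bound = np.sqrt(6.0 / (fi + fo))
                assert np.abs(tiny_params[name]).max() <= bound

    def test_variance_matches_glorot(self):
        layer = Dense("d", 1000, 1000)

        class OneLayerModel:
            def param_specs(self):
                return layer.param_specs()

        params = init_parameters(OneLayerModel(), 0)
        var = params["d/W"].var()
        assert abs(var - 2.0 / 2000) / (2.0 / 2000) < 0.05


TOY_CONFIG = dict(
    protein_shape=(20, 48), ligand_shape=(64, 24),
    protein_block_channels=(8, 8, 8), ligand_block_channels=(8, 8, 8),
    embedding_dim=16, dense_units=(16, 8, 1), dropout_rate_range=(0.0, 0.0),
)


def _toy_batches(rng, n=160, n_val=48):
    """Cleanly separable toy problem: positives carry a planted block of
    token 0, negatives carry no token 0 at all."""
    total = n + n_val
    Xp = random_onehot(rng, 20, 48, total)
    Xl = random_onehot(rng, 64, 24, total)
    y = rng.integers(0, 2, total).astype(float)
    for i in range(total):
        hits = np.flatnonzero(Xp[i, 0, :])
        Xp[i, 0, hits] = 0.0
        Xp[i, 2, hits] = 1.0  # scrub stray token-0 columns
        if y[i] == 1:
            Xp[i, :, 10:18] = 0.0
            Xp[i, 0, 10:18] = 1.0
    train = LabeledBatch(Xp[:n], Xl[:n], y[:n], "classification")
    val = LabeledBatch(Xp[n:], Xl[n:], y[n:], "classification")
    return train, val


def _small_model():
    model = PLIModel(ModelConfig(**{**TINY_MODEL_CONFIG,
                                    "dropout_rate_range": (0.0, 0.0)}))
    return model


class TestTrainSingleTask:
    def test_learns_separable_toy_problem(self, rng):
        train, val = _toy_batches(rng, n=192, n_val=64)
        model = PLIModel(ModelConfig(**TOY_CONFIG))
        cfg = TrainConfig(learning_rate=3e-3, batch_size=32, max_epochs=25,
                          patience=25, seed=0)
        params, log = train_single_task(train, val, model, cfg)
        df = log.to_dataframe()
        assert df.train_loss.iloc[0] > df.train_loss.iloc[3]  # loss decreases
        preds = model.predict(train.Xp, train.Xl, params, "classification")
        acc = np.mean((preds > 0.5) == train.y)
        assert acc > 0.95

    def test_patience_zero_stops_after_first_nonimprovement(self, rng):
        train, val = _toy_batches(rng, n=64, n_val=32)
        model = _small_model()
        cfg = TrainConfig(learning_rate=1e-2, batch_size=32, max_epochs=30,
                          patience=0, seed=0)
        _, log = train_single_task(train, val, model, cfg)
        vlosses = log.val_losses("classification")
        best = np.inf
        stop_epoch = None
        for i, v in enumerate(vlosses, start=1):
            if v < best:
                best = v
            else:
                stop_epoch = i
                break
        if stop_epoch is not None:
            assert len(vlosses) == stop_epoch  # exactly 1 epoch beyond

    def test_selected_epoch_minimizes_val_loss(self, rng):
        train, val = _toy_batches(rng, n=64, n_val=32)
        model = _small_model()
        cfg = TrainConfig(learning_rate=3e-3, batch_size=32, max_epochs=8,
                          patience=8, seed=0)
        _, log = train_single_task(train, val, model, cfg)
        vlosses = log.val_losses("classification")
        assert log.selected_epoch["classification"] == int(np.argmin(vlosses)) + 1

    def test_seeded_determinism(self, rng):
        train, val = _toy_batches(rng, n=64, n_val=32)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=32, max_epochs=3,
                          patience=5, seed=11)
        logs = []
        for _ in range(2):
            model = PLIModel(ModelConfig(**TINY_MODEL_CONFIG))  # dropout active
            _, log = train_single_task(train, val, model, cfg)
            logs.append(log.to_dataframe())
        assert logs[0].equals(logs[1])

    def test_empty_data_rejected(self, rng):
        train, val = _toy_batches(rng, n=16, n_val=8)
        with pytest.raises(ValueError):
            LabeledBatch(train.Xp[:0], train.Xl[:0], train.y[:0], "classification")


def _multi_batches(rng, n=96):
    Xp = random_onehot(rng, 20, 48, 2 * n)
    Xl = random_onehot(rng, 64, 24, 2 * n)
    signal = Xp[:, 0, :].sum(axis=1) - Xp[:, 1, :].sum(axis=1)
    y_cls = (signal > 0).astype(float)
    y_reg = 5.0 + 0.5 * signal
    cls = LabeledBatch(Xp[:n], Xl[:n], y_cls[:n], "classification")
    reg = LabeledBatch(Xp[n:], Xl[n:], y_reg[n:], "regression")
    val_cls = LabeledBatch(Xp[n // 2 : n], Xl[n // 2 : n], y_cls[n // 2 : n],
                           "classification")
    val_reg = LabeledBatch(Xp[n + n // 2 :], Xl[n + n // 2 :], y_reg[n + n // 2 :],
                           "regression")
    return cls, reg, val_cls, val_reg


class TestMultiTaskBranchIsolation:
    def test_single_steps_touch_only_active_head(self, rng):
        """After a classification batch the regression head is bit-identical
        (and vice versa) while shared weights move."""
        from plinet.training import Adam, _task_step
        model = PLIModel(ModelConfig(**TINY_MODEL_CONFIG))
        params = init_parameters(model, 0)
        cls, reg, _, _ = _multi_batches(rng)
        opt = Adam(1e-3)
        srng = np.random.default_rng(0)

        before = PLIModel.copy_params(params)
        _task_step(model, params, opt, cls.subset(np.arange(16)), 1e-4, srng)
        for key in model.head_param_names("regression"):
            assert np.array_equal(params[key], before[key])
        assert any(not np.array_equal(params[k], before[k])
                   for k in params if k.startswith("trunk/"))
        changed_cls = any(not np.array_equal(params[k], before[k])
                          for k in model.head_param_names("classification"))
        assert changed_cls

        before = PLIModel.copy_params(params)
        _task_step(model, params, opt, reg.subset(np.arange(16)), 1e-4, srng)
        for key in model.head_param_names("classification"):
            assert np.array_equal(params[key], before[key])

    def test_full_training_returns_per_task_snapshots(self, rng):
        cls, reg, vc, vr = _multi_batches(rng)
        model = _small_model()
        cfg = TrainConfig(learning_rate=3e-3, batch_size=32, max_epochs=5,
                          patience=5, seed=0)
        best, log = train_multi_task(cls, reg, vc, vr, model, cfg)
        assert set(best) == {"classification", "regression"}
        assert set(log.selected_epoch) == {"classification", "regression"}
        df = log.to_dataframe()
        assert set(df.task) == {"classification", "regression"}
        # both validation losses improve over their first epoch
        for task in ("classification", "regression"):
            v = log.val_losses(task)
            assert min(v) <= v[0]

    def test_missing_validation_rejected(self, rng):
        cls, reg, vc, vr = _multi_batches(rng)
        model = _small_model()
        cfg = TrainConfig(max_epochs=1)
        with pytest.raises(ValueError, match="validation"):
            train_multi_task(cls, reg, None, vr, model, cfg)

    def test_task_stream_roles_checked(self, rng):
        cls, reg, vc, vr = _multi_batches(rng)
        model = _small_model()
        with pytest.raises(ValueError):
            train_multi_task(reg, cls, vr, vc, model, TrainConfig(max_epochs=1))


class TestAdam:
    def test_untouched_parameters_keep_state(self):
        opt = Adam(0.1)
        params = {"a": np.ones(2), "b": np.ones(2)}
        opt.update(params, {"a": np.full(2, 0.5)})
        assert np.array_equal(params["b"], np.ones(2))
        assert "b" not in opt.t
        # second update of a advances only a's clock
        opt.update(params, {"a": np.full(2, 0.5)})
        assert opt.t["a"] == 2
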