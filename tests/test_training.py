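"""Training loop protocol: checkpointing, patience rules, prediction."""

import numpy as np
import pytest

import cgmbench as cb
from cgmbench.nn import Module, Tensor


def _window_set(inputs, targets, L=24, p=6):
    return cb.WindowSet(np.asarray(inputs, float), np.asarray(targets, float),
                        L, p, ["p"] * len(targets), np.arange(len(targets)))


@pytest.fixture(scope="module")
def sinusoid_windows():
    """A learnable noiseless signal: windows of a slow sine on the 5-min grid."""
    t = np.arange(3000)
    values = np.sin(2 * np.pi * t / 96)          # 8-hour period
    seg = cb.Segment("s", 0, values + 2.0, np.zeros(len(values), bool))
    params = cb.NormalizationParams(mu=2.0, sigma=float(values.std(ddof=0)))
    ws = cb.make_windows([seg], L=24, horizons=[6], params=params)[6]
    n = ws.n_windows
    cut = int(0.8 * n)
    train = cb.WindowSet(ws.inputs[:cut], ws.targets[:cut], 24, 6,
                         ws.patient_ids[:cut], ws.starts[:cut])
    val = cb.WindowSet(ws.inputs[cut:], ws.targets[cut:], 24, 6,
                       ws.patient_ids[cut:], ws.starts[cut:])
    return train, val, params


class _LastValueModel(Module):
    """Echoes the final history step; used to probe prediction plumbing."""

    def forward(self, x: Tensor) -> Tensor:
        return x[:, -1, :]


def test_zero_epochs_returns_initialization(sinusoid_windows):
    train, val, _ = sinusoid_windows
    spec = cb.default_specs()["FFN"]
    cfg = cb.TrainConfig(epochs=0, batch_size=64, repetitions=1)
    trained = cb.train_model(spec, train, val, cfg, seed=5)
    init = cb.build_model(spec, 5)
    for a, b in zip(trained.model.parameters(), init.parameters()):
        np.testing.assert_array_equal(a.data, b.data)
    assert trained.history.train_loss == []
    assert trained.history.stop_epoch == 0


def test_empty_split_rejected(sinusoid_windows):
    train, val, _ = sinusoid_windows
    empty = _window_set(np.zeros((0, 24)), np.zeros(0))
    cfg = cb.TrainConfig(epochs=1, batch_size=8)
    with pytest.raises(ValueError):
        cb.train_model(cb.default_specs()["FFN"], empty, val, cfg, seed=0)


def test_learnable_signal_improves_validation(sinusoid_windows):
    """On a noiseless sinusoid the LSTM's validation RMSE drops within a few
    epochs of its starting value."""
    train, val, _ = sinusoid_windows
    cfg = cb.TrainConfig(epochs=4, batch_size=128, repetitions=1,
                         max_train_windows=1500)
    trained = cb.train_model(cb.default_specs()["LSTM"], train, val, cfg, seed=0)
    assert trained.history.val_rmse[-1] < trained.history.val_rmse[0]
    assert trained.history.best_epoch >= 0


def test_early_stopping_on_plateau(sinusoid_windows):
    """With a zero learning rate the model never improves after epoch one,
    so training stops exactly early_stop_patience epochs later."""
    train, val, _ = sinusoid_windows
    small_train = cb.WindowSet(train.inputs[:64], train.targets[:64], 24, 6,
                               train.patient_ids[:64], train.starts[:64])
    cfg = cb.TrainConfig(epochs=50, batch_size=64, learning_rate=0.0,
                         lr_decay_patience=3, early_stop_patience=5)
    trained = cb.train_model(cb.default_specs()["FFN"], small_train, val, cfg, seed=1)
    assert trained.history.stop_epoch == 1 + 5        # best at epoch 0, then 5 flat
    assert trained.history.best_epoch == 0


def test_injected_plateau_traces_decay_and_stop(monkeypatch, sinusoid_windows):
    """A validation plateau injected from epoch 2 onward: training must stop
    exactly early_stop_patience epochs after the last improvement, and the
    learning rate must decay every lr_decay_patience flat epochs."""
    import cgmbench.training as training
    vals = iter([5.0, 4.0] + [4.5] * 60)
    monkeypatch.setattr(training, "_eval_rmse", lambda m, w: next(vals))
    train, val, _ = sinusoid_windows
    small_train = cb.WindowSet(train.inputs[:64], train.targets[:64], 24, 6,
                               train.patient_ids[:64], train.starts[:64])
    cfg = cb.TrainConfig(epochs=50, batch_size=64, learning_rate=1e-3,
                         lr_decay_patience=3, early_stop_patience=6)
    trained = cb.train_model(cb.default_specs()["FFN"], small_train, val, cfg, seed=1)
    assert trained.history.best_epoch == 1
    assert trained.history.stop_epoch == 2 + 6       # plateau starts at epoch 2
    # lr is recorded before the patience bookkeeping of the same epoch:
    # decays land at flat epochs 4 and 7, visible one epoch later
    assert trained.history.lr_trace[4] == pytest.approx(1e-3)
    assert trained.history.lr_trace[5] == pytest.approx(1e-4)
    assert trained.history.lr_trace[-1] == pytest.approx(1e-4)


def test_checkpoint_has_minimum_validation_rmse(sinusoid_windows):
    train, val, _ = sinusoid_windows
    cfg = cb.TrainConfig(epochs=5, batch_size=128, repetitions=1,
                         max_train_windows=1000)
    trained = cb.train_model(cb.default_specs()["FFN"], train, val, cfg, seed=3)
    from cgmbench.training import _eval_rmse
    restored = _eval_rmse(trained.model, val)
    assert restored == pytest.approx(min(trained.history.val_rmse), abs=1e-9)


def test_seeded_determinism(sinusoid_windows):
    train, val, _ = sinusoid_windows
    cfg = cb.TrainConfig(epochs=2, batch_size=128, max_train_windows=500)
    a = cb.train_model(cb.default_specs()["FFN"], train, val, cfg, seed=9)
    b = cb.train_model(cb.default_specs()["FFN"], train, val, cfg, seed=9)
    assert a.history.val_rmse == b.history.val_rmse
    for pa, pb in zip(a.model.parameters(), b.model.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)


class TestPredict:
    def test_persistence_probe_returns_last_history_value(self):
        params = cb.NormalizationParams(mu=150.0, sigma=40.0)
        inputs = np.random.default_rng(0).normal(size=(10, 24))
        targets = np.random.default_rng(1).normal(size=10)
        ws = _window_set(inputs, targets)
        ps = cb.predict(_LastValueModel(), ws, params)
        np.testing.assert_allclose(
            ps.preds, cb.invert_normalizer(params, inputs[:, -1]), atol=1e-12)

    def test_empty_window_set_gives_empty_predictions(self):
        params = cb.NormalizationParams(mu=150.0, sigma=40.0)
        ws = _window_set(np.zeros((0, 24)), np.zeros(0))
        ps = cb.predict(_LastValueModel(), ws, params)
        assert ps.N == 0

    def test_references_denormalize_to_original_values(self, small_datasets):
        """De-normalized window targets recover the segment glucose exactly."""
        params = small_datasets["params"]
        ws = small_datasets["windows"]["test"][6]
        refs = cb.invert_normalizer(params, ws.targets)
        seg_values = np.concatenate(
            [s.values for s in small_datasets["segments"]["test"]])
        assert np.all(np.isin(np.round(refs, 6), np.round(seg_values, 6)))
        ps = cb.predict(_LastValueModel(), ws, params)
        np.testing.assert_allclose(ps.refs, refs, atol=1e-6)

    def test_window_length_mismatch_rejected(self):
        params = cb.NormalizationParams(mu=0.0, sigma=1.0)
        ws = _window_set(np.zeros((3, 12)), np.zeros(3), L=12)
        model = cb.build_model(cb.default_specs()["FFN"], 0)
        with pytest.raises(ValueError):
            cb.predict(model, ws, params)


@pytest.fixture(scope="module")
def repeat_result(sinusoid_windows):
    train, val, _ = sinusoid_windows
    params = cb.NormalizationParams(mu=2.0, sigma=0.7)
    cfg = cb.TrainConfig(epochs=1, batch_size=128, repetitions=3,
                         base_seed=10, max_train_windows=400)
    return cb.repeat_runs(cb.default_specs()["FFN"], train, val, val,
                          params, cfg)


class TestRepeatRuns:
    def test_aggregate_is_arithmetic_mean(self, repeat_result):
        rmses = [r.rmse for r in repeat_result["reports"]]
        assert repeat_result["aggregate"]["rmse"]["mean"] == pytest.approx(
            float(np.mean(rmses)), abs=1e-12)

    def test_seeds_are_consecutive_from_base(self, repeat_result):
        assert [r.seed for r in repeat_result["runs"]] == [10, 11, 12]

    def test_single_repetition_reports_zero_std(self, sinusoid_windows):
        train, val, _ = sinusoid_windows
        params = cb.NormalizationParams(mu=2.0, sigma=0.7)
        cfg = cb.TrainConfig(epochs=1, batch_size=128, repetitions=1,
                             max_train_windows=300)
        res = cb.repeat_runs(cb.default_specs()["FFN"], train, val, val,
                             params, cfg)
        assert res["aggregate"]["rmse"]["std"] == 0.0


def test_checkpoint_round_trip(tmp_path, sinusoid_windows):
    train, val, _ = sinusoid_windows
    cfg = cb.TrainConfig(epochs=1, batch_size=128, max_train_windows=300)
    trained = cb.train_model(cb.default_specs()["FFN"], train, val, cfg, seed=2)
    from cgmbench.training import load_checkpoint, save_checkpoint
    save_checkpoint(trained, tmp_path / "ffn.npz")
    back = load_checkpoint(tmp_path / "ffn.npz")
    assert back.spec == trained.spec
    assert back.history.val_rmse == trained.history.val_rmse
    for a, b in zip(trained.model.parameters(), back.model.parameters()):
        np.testing.assert_array_equal(a.data, b.data)
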