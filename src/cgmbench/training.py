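"""Training protocol: Adam on batch-averaged RMSE with plateau decay,
early stopping, best-checkpoint restore, and repeated seeded runs.

Each epoch runs standard minibatch gradient descent (one Adam step per
batch) on the RMSE of normalized targets; the epoch's reported training
loss is the mean of the per-batch RMSE values.  After each epoch the
validation RMSE is computed; the learning rate is multiplied by 0.1 after
10 epochs without improvement, training stops after 30 epochs without
improvement (the two patience counters run independently, both reset on any
strict improvement), and the parameters from the best validation epoch are
restored at the end.  A full run is 100 epochs with five repeated seeds;
desk-scale runs shorten both.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricReport, PredictionSet, evaluate_metrics
from .models import ModelSpec, build_model, predict_array
from .nn import Adam, Module, Tensor
from .preprocess import NormalizationParams, WindowSet, invert_normalizer

__all__ = [
    "TrainConfig", "TrainHistory", "TrainedModel",
    "train_model", "repeat_runs", "predict", "persistence_baseline",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16              # 16 / 512 / 1024 depending on cohort size
    learning_rate: float | None = None    # None: use the spec's tuned rate
    lr_decay_factor: float = 0.1
    lr_decay_patience: int = 10
    early_stop_patience: int = 30
    repetitions: int = 5
    base_seed: int = 0
    max_train_windows: int | None = None  # optional subsample for desk-scale runs

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.repetitions < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)   # batch-averaged RMSE
    val_rmse: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_epoch: int = 0
    seconds: float = 0.0


@dataclass
class TrainedModel:
    model: Module
    spec: ModelSpec
    seed: int
    history: TrainHistory


def _batch_rmse(model: Module, x: np.ndarray, y: np.ndarray) -> Tensor:
    out = model(Tensor(x[:, :, None]))
    diff = out - Tensor(y[:, None])
    return ((diff * diff).mean()) ** 0.5


def _eval_rmse(model: Module, windows: WindowSet) -> float:
    preds = predict_array(model, windows.inputs)
    return float(np.sqrt(np.mean((preds - windows.targets) ** 2)))


def train_model(spec: ModelSpec, train: WindowSet, val: WindowSet,
                config: TrainConfig, seed: int) -> TrainedModel:
    """Train one model instance; deterministic given (spec, config, seed)."""
    if train.n_windows == 0 or val.n_windows == 0:
        raise ValueError("empty train or validation window set")
    rng = np.random.default_rng(seed)
    model = build_model(spec, seed)
    lr = config.learning_rate if config.learning_rate is not None else spec.learning_rate
    opt = Adam(model.parameters(), lr=lr)
    history = TrainHistory()
    t_start = time.perf_counter()

    X, y = train.inputs, train.targets
    if config.max_train_windows is not None and len(y) > config.max_train_windows:
        pick = rng.choice(len(y), size=config.max_train_windows, replace=False)
        X, y = X[pick], y[pick]

    best_val = np.inf
    best_state = model.state_dict()
    decay_wait = stop_wait = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        batch_losses = []
        for lo in range(0, len(y), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss = _batch_rmse(model, X[idx], y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(batch_losses)))
        v = _eval_rmse(model, val)
        history.val_rmse.append(v)
        history.lr_trace.append(opt.lr)
        history.stop_epoch = epoch + 1
        if v < best_val:
            best_val = v
            best_state = model.state_dict()
            history.best_epoch = epoch
            decay_wait = stop_wait = 0
        else:
            decay_wait += 1
            stop_wait += 1
            if decay_wait >= config.lr_decay_patience:
                opt.lr *= config.lr_decay_factor
                decay_wait = 0
            if stop_wait >= config.early_stop_patience:
                break
    model.load_state_dict(best_state)
    history.seconds = time.perf_counter() - t_start
    return TrainedModel(model=model, spec=spec, seed=seed, history=history)


def predict(trained: TrainedModel | Module, windows: WindowSet,
            params: NormalizationParams, context: dict | None = None,
            sex_by_patient: dict[str, str] | None = None) -> PredictionSet:
    """Forecast every window and de-normalize both sides back to mg/dL."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    spec = getattr(model, "spec", None)
    if spec is not None and windows.inputs.shape[1] != spec.input_length:
        raise ValueError("window length L does not match the model's input length")
    z = predict_array(model, windows.inputs)
    sex_labels = None
    if sex_by_patient is not None:
        sex_labels = [sex_by_patient[pid] for pid in windows.patient_ids]
    return PredictionSet(
        refs=invert_normalizer(params, windows.targets),
        preds=invert_normalizer(params, z),
        context=context or {}, sex_labels=sex_labels,
    )


def persistence_baseline(windows: WindowSet, params: NormalizationParams,
                         context: dict | None = None) -> PredictionSet:
    """Last-observed-value forecast, the naive competitor at short horizons."""
    return PredictionSet(
        refs=invert_normalizer(params, windows.targets),
        preds=invert_normalizer(params, windows.inputs[:, -1]),
        context={**(context or {}), "model": "persistence"},
    )


def save_checkpoint(trained: TrainedModel, path) -> None:
    """Weights as an ``.npz`` plus a JSON sidecar with spec, seed and history."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, *trained.model.state_dict())
    sidecar = {
        "spec": dataclasses.asdict(trained.spec),
        "seed": trained.seed,
        "history": dataclasses.asdict(trained.history),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path) -> TrainedModel:
    """Rebuild a :class:`TrainedModel` from :func:`save_checkpoint` output."""
    import json
    from pathlib import Path

    from .models import build_model

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    spec_kwargs = sidecar["spec"]
    for key, value in spec_kwargs.items():
        if isinstance(value, list):
            spec_kwargs[key] = tuple(value)
    spec = ModelSpec(**spec_kwargs)
    model = build_model(spec, sidecar["seed"])
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict([data[k] for k in data.files])
    history = TrainHistory(**sidecar["history"])
    return TrainedModel(model=model, spec=spec, seed=sidecar["seed"],
                        history=history)


def repeat_runs(spec: ModelSpec, train: WindowSet, val: WindowSet,
                test: WindowSet, params: NormalizationParams,
                config: TrainConfig) -> dict:
    """Train ``config.repetitions`` seeds and aggregate test metrics.

    Returns per-run reports plus mean and standard deviation (population,
    over runs) of each metric, in the mean +/- SD style of the study tables.
    """
    runs: list[TrainedModel] = []
    reports: list[MetricReport] = []
    for rep in range(config.repetitions):
        trained = train_model(spec, train, val, config, seed=config.base_seed + rep)
        runs.append(trained)
        reports.append(evaluate_metrics(predict(trained, test, params)))
    agg = {}
    for key in ("rmse", "mad", "cod", "fit", "madp"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        agg[key] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=0))}
    return {"runs": runs, "reports": reports, "aggregate": agg}
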