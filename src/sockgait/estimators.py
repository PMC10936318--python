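"""The three angle-estimator families and their training regime.

* Multivariable linear regression maps the instantaneous 12-vector of
  features to the two angles, solved in closed form by the normal equations
  (an 80/20 contiguous train/test split, no validation set).
* The LSTM and CNN families consume sliding windows (12 x N) and emit the
  two angles at the window's final timestep.  Both train for 40 epochs with
  Adam on a mean-absolute-error loss, the learning rate decaying linearly
  from 0.05 to 0.04, and keep the parameters of the epoch with the best
  validation MAE.

Reference architectures:

* base LSTM — LSTM(128) -> LSTM(64) -> Dropout(0.3) -> Dense(2);
* best LSTM — LSTM(64) -> LSTM(32) -> Dropout(0.2) -> Dense(2);
* base CNN — Conv(50, k3) x2 -> MaxPool(2,1) -> Conv(100, k3) x2 ->
  Flatten -> Dense(100, relu) -> Dense(2);

with hyperparameter search spaces of 32/64/128 recurrent units, dropout
0.2/0.3/0.4, 50-256 filters, kernels (3,1)/(5,1), Glorot uniform/normal
initialisers and ReLU/LeakyReLU activations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from . import nn
from .errors import ConfigError, RankDeficientError, TrainingDivergedError

LSTM_UNIT_GRID = (32, 64, 128)
DROPOUT_GRID = (0.2, 0.3, 0.4)
CNN_FILTER_RANGE = (50, 256)
KERNEL_GRID = (3, 5)

OUTPUT_SIZE = 2


@dataclass(frozen=True)
class ModelSpec:
    """Declarative estimator description.

    ``layers`` is an ordered list of descriptor dicts, e.g.
    ``{"lstm": 64}``, ``{"conv": 50, "kernel": 3, "activation": "relu"}``,
    ``{"pool": 2}``, ``{"dropout": 0.3}``, ``{"flatten": True}``,
    ``{"dense": 100, "activation": "relu"}``.  The final layer must be a
    dense layer of size 2 (FLX, INV).
    """

    family: str
    layers: tuple
    input_n: int
    input_channels: int = 12

    def __post_init__(self):
        if self.family not in ("linear", "lstm", "cnn"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family != "linear":
            if not self.layers:
                raise ConfigError("layer list is empty")
            last = self.layers[-1]
            if last.get("dense") != OUTPUT_SIZE:
                raise ConfigError("output layer must be dense of size 2")


def lstm_base_spec(n: int) -> ModelSpec:
    return ModelSpec("lstm", (
        {"lstm": 128}, {"lstm": 64}, {"dropout": 0.3}, {"dense": OUTPUT_SIZE},
    ), input_n=n)


def lstm_best_spec(n: int) -> ModelSpec:
    return ModelSpec("lstm", (
        {"lstm": 64}, {"lstm": 32}, {"dropout": 0.2}, {"dense": OUTPUT_SIZE},
    ), input_n=n)


def cnn_base_spec(n: int, kernel: int = 3, activation: str = "leaky_relu") -> ModelSpec:
    # LeakyReLU (in the conv search space) is the default: with the aggressive
    # 0.05 starting rate, plain ReLU units can die en masse in the first Adam
    # steps and freeze the net at the mean predictor.
    return ModelSpec("cnn", (
        {"conv": 50, "kernel": kernel, "activation": activation},
        {"conv": 50, "kernel": kernel, "activation": activation},
        {"pool": 2},
        {"conv": 100, "kernel": kernel, "activation": activation},
        {"conv": 100, "kernel": kernel, "activation": activation},
        {"flatten": True},
        {"dense": 100, "activation": activation}, {"dense": OUTPUT_SIZE},
    ), input_n=n)


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate an untrained model from a spec.

    The layer sequence, unit/filter counts and kernel/pool shapes follow the
    spec exactly; the parameter count is a pure function of the spec and is
    available as ``model.num_params()``.  Raises
    :class:`~sockgait.errors.ModelShapeError` naming the offending layer if a
    kernel outgrows the remaining time dimension.
    """
    if spec.family == "linear":
        raise ConfigError("linear models are fitted with fit_linear, not built")
    layers = []
    descs = list(spec.layers)
    for idx, d in enumerate(descs):
        name = f"layer{idx}"
        if "lstm" in d:
            later_lstm = any("lstm" in d2 for d2 in descs[idx + 1:])
            layers.append(nn.LSTM(
                d["lstm"], return_sequences=later_lstm,
                init=d.get("init", "glorot_uniform"), name=f"{name}:lstm",
            ))
        elif "conv" in d:
            layers.append(nn.ConvTime(
                d["conv"], d.get("kernel", 3),
                activation=d.get("activation", "relu"),
                init=d.get("init", "glorot_uniform"), name=f"{name}:conv",
            ))
        elif "pool" in d:
            layers.append(nn.MaxPoolTime(d["pool"], name=f"{name}:pool"))
        elif "dropout" in d:
            layers.append(nn.Dropout(d["dropout"], name=f"{name}:dropout"))
        elif "flatten" in d:
            layers.append(nn.Flatten())
        elif "dense" in d:
            layers.append(nn.Dense(
                d["dense"], activation=d.get("activation"),
                init=d.get("init", "glorot_uniform"), name=f"{name}:dense",
            ))
        else:
            raise ConfigError(f"unrecognised layer descriptor {d!r}")
    return nn.Sequential(layers, (spec.input_n, spec.input_channels), seed=seed)


@dataclass
class TrainConfig:
    """Training settings: Adam, MAE loss, linear 0.05 -> 0.04 decay, 40 epochs."""

    epochs: int = 40
    lr_start: float = 0.05
    lr_end: float = 0.04
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0:
            raise ConfigError("epochs must be positive")
        if not self.lr_start >= self.lr_end > 0:
            raise ConfigError("need lr_start >= lr_end > 0")

    def lr_at(self, epoch: int) -> float:
        if self.epochs == 1:
            return self.lr_start
        frac = epoch / (self.epochs - 1)
        return self.lr_start + (self.lr_end - self.lr_start) * frac


def _to_time_major(inputs: np.ndarray) -> np.ndarray:
    """(M, C, N) frames -> (M, N, C) tensors for the nn engine."""
    return np.ascontiguousarray(np.swapaxes(inputs, 1, 2))


def train(model: nn.Sequential, train_xy, val_xy, config: TrainConfig) -> dict:
    """Train a model on framed data; restore the best-validation parameters.

    ``train_xy``/``val_xy`` are ``(inputs (M, C, N), targets (M, 2))``.
    Returns a history dict with per-epoch ``train_loss``, ``val_loss`` and
    ``lr``, plus ``best_epoch`` and ``best_val``.  Raises
    :class:`TrainingDivergedError` on a non-finite loss.
    """
    Xtr, Ytr = _to_time_major(np.asarray(train_xy[0])), np.asarray(train_xy[1])
    Xva, Yva = _to_time_major(np.asarray(val_xy[0])), np.asarray(val_xy[1])
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ConfigError("train and validation partitions must be nonempty")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_epoch = -1
    best_weights = model.get_weights()

    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            pred = model.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(np.abs(err)))
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            model.backward(np.sign(err) / err.size)
            opt.step(lr)
            losses.append(loss)
        val_loss = float(np.mean(np.abs(_forward_batched(model, Xva) - Yva)))
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val"] = best_val
    return history


def _forward_batched(model, X, batch=1024):
    outs = [model.forward(X[i:i + batch], train=False) for i in range(0, len(X), batch)]
    return np.concatenate(outs) if outs else np.empty((0, OUTPUT_SIZE))


def predict(model: nn.Sequential, inputs: np.ndarray, batch: int = 1024) -> np.ndarray:
    """Deterministic inference (dropout inactive) on (M, C, N) frames."""
    inputs = np.asarray(inputs)
    if inputs.shape[2] != model.input_shape[0]:
        raise ConfigError(
            f"frame window {inputs.shape[2]} does not match model N {model.input_shape[0]}"
        )
    return _forward_batched(model, _to_time_major(inputs), batch)


@dataclass
class LinearAngleModel:
    """Closed-form multivariable regression: 12 features + intercept -> 2 angles."""

    coef: np.ndarray        # (13, 2); row 0 is the intercept
    feature_names: tuple = field(default=())

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.coef[0] + X @ self.coef[1:]


def fit_linear(X: np.ndarray, Y: np.ndarray, feature_names=None) -> LinearAngleModel:
    """Least-squares fit of the two angles on instantaneous feature vectors.

    Solves the normal equations exactly; raises
    :class:`RankDeficientError` naming the collinear channels (found by
    pivoted QR) if the design matrix is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
        raise ConfigError("X must be (M, p) and Y (M, 2) with matching M")
    M, p = X.shape
    if M < p + 1:
        raise ConfigError(f"need at least {p + 1} training rows, got {M}")
    names = tuple(feature_names) if feature_names else tuple(
        f"x{i}" for i in range(p)
    )
    D = np.hstack([np.ones((M, 1)), X])
    G = D.T @ D
    _, R, piv = sla.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    dead = piv[np.flatnonzero(diag <= tol)]
    if dead.size:
        labels = ["intercept" if j == 0 else names[j - 1] for j in sorted(dead)]
        raise RankDeficientError(labels)
    coef = np.linalg.solve(G, D.T @ Y)
    return LinearAngleModel(coef=coef, feature_names=names)
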