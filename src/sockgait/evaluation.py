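"""Training strategies, evaluation metrics and study reporting.

Three strategy designs control which trials supply training vs. test data:

* speed-specific — train and test come from one single-speed trial's own
  contiguous 60/20/20 (or 80/20 for regression) split;
* multi-speed — train on every speed's train range, test on every speed's
  test range;
* speed-independent — train on every speed's train range, test on a single
  speed's test range.

Train and test never share timesteps: the split is contiguous in time within
each trial, and strategies only select whole split ranges.

Metrics per output channel: MAE and RMSE in degrees, and R^2 computed as
``1 - SSE/SST`` about the true mean over the concatenated test timesteps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .estimators import (
    TrainConfig,
    build_model,
    fit_linear,
    lstm_best_spec,
    predict,
    train,
)
from .framing import FrameDataset, frames_from_trial
from .prep import TARGET_NAMES, normalize_trials

STRATEGIES = ("speed-specific", "multi-speed", "speed-independent")


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-channel MAE, RMSE and R^2 for (M, 2) true/predicted angles."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 2 or len(y_true) < 2:
        raise ConfigError("y_true and y_pred must be equal (M>=2, K) arrays")
    err = y_pred - y_true
    sst = np.sum((y_true - y_true.mean(axis=0)) ** 2, axis=0)
    if np.any(sst == 0):
        bad = [TARGET_NAMES[i] if i < len(TARGET_NAMES) else str(i)
               for i in np.flatnonzero(sst == 0)]
        raise DegenerateInputError(
            f"R^2 undefined for constant channel(s): {', '.join(bad)}"
        )
    return {
        "mae": np.mean(np.abs(err), axis=0),
        "rmse": np.sqrt(np.mean(err ** 2, axis=0)),
        "r2": 1.0 - np.sum(err ** 2, axis=0) / sst,
    }


@dataclass(frozen=True)
class StrategySpec:
    """A training-strategy design; ``speed`` selects the single-speed trial
    for speed-specific training or the speed-independent test speed."""

    name: str
    speed: float | str | None = None

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.name!r}")
        if self.name != "multi-speed" and self.speed is None:
            raise ConfigError(f"{self.name} needs a speed selector")


def assemble(strategy: StrategySpec, frames_by_speed: dict):
    """Select (train, val, test) frame sets for a strategy.

    ``frames_by_speed`` maps speed label -> :class:`FrameDataset` (framed
    with each trial's own split).  Raises :class:`ConfigError` naming the
    missing trial if a required speed is absent.
    """
    if not frames_by_speed:
        raise ConfigError("no trials supplied")

    def _need(speed):
        if speed not in frames_by_speed:
            raise ConfigError(f"missing trial for speed {speed!r}")
        return frames_by_speed[speed]

    if strategy.name == "speed-specific":
        f = _need(strategy.speed)
        return f.subset("train"), f.subset("val"), f.subset("test")
    all_frames = list(frames_by_speed.values())
    tr = FrameDataset.concat([f.subset("train") for f in all_frames])
    va = FrameDataset.concat([f.subset("val") for f in all_frames])
    if strategy.name == "multi-speed":
        te = FrameDataset.concat([f.subset("test") for f in all_frames])
    else:
        te = _need(strategy.speed).subset("test")
    return tr, va, te


def _linear_xy(trial, ranges):
    """Stack (features.T, targets.T) over the named split ranges of a trial."""
    xs, ys = [], []
    for r in ranges:
        s, e = trial.split[r]
        xs.append(trial.features[:, s:e].T)
        ys.append(trial.targets[:, s:e].T)
    return np.concatenate(xs), np.concatenate(ys)


def assemble_linear(strategy: StrategySpec, trials_by_speed: dict):
    """Timestep-level (train, test) pairs for the regression family.

    Regression uses the first 80% of timesteps (the train + val ranges of
    the 60/20/20 split) for fitting and the last 20% for testing, with no
    validation set.
    """
    if not trials_by_speed:
        raise ConfigError("no trials supplied")

    def _need(speed):
        if speed not in trials_by_speed:
            raise ConfigError(f"missing trial for speed {speed!r}")
        return trials_by_speed[speed]

    train_ranges = ("train", "val")
    if strategy.name == "speed-specific":
        t = _need(strategy.speed)
        return _linear_xy(t, train_ranges), _linear_xy(t, ("test",))
    trains = [_linear_xy(t, train_ranges) for t in trials_by_speed.values()]
    tr = tuple(np.concatenate(parts) for parts in zip(*trains))
    if strategy.name == "multi-speed":
        tests = [_linear_xy(t, ("test",)) for t in trials_by_speed.values()]
        te = tuple(np.concatenate(parts) for parts in zip(*tests))
    else:
        te = _linear_xy(_need(strategy.speed), ("test",))
    return tr, te


def run_study(
    participants: dict,
    strategies,
    families,
    N: int = 90,
    train_config: TrainConfig | None = None,
    spec_factory=None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Train and evaluate every (participant, strategy, family) cell.

    ``participants`` maps participant id -> dict of speed label ->
    :class:`~sockgait.prep.AlignedTrial` (all trials of one foot).  Trials
    are normalized per participant on their pooled train ranges; reported
    errors are inverse-transformed back to degrees.  Models trained on
    identical data within a participant (multi-speed and speed-independent
    share training sets) are fitted once and reused.  Returns one
    long-format row per (participant, foot, strategy, speed, family,
    channel) with equal-trial weighting left to the caller's aggregation.
    """
    train_config = train_config or TrainConfig()
    spec_factory = spec_factory or (lambda fam, n: lstm_best_spec(n))
    rows = []
    for pid, trials_by_speed in participants.items():
        trials = list(trials_by_speed.values())
        if normalize:
            _, (f_scaler, y_scaler) = normalize_trials(trials)
        else:
            y_scaler = None
        frames_by_speed = {
            sp: frames_from_trial(t, N, trial_id=i)
            for i, (sp, t) in enumerate(trials_by_speed.items())
        }
        foot = trials[0].foot
        cache = {}
        for family in families:
            for strat in strategies:
                # multi-speed and speed-independent share one training set
                key = (family, f"specific:{strat.speed}"
                       if strat.name == "speed-specific" else "all-speeds")
                if family == "linear":
                    (Xtr, Ytr), (Xte, Yte) = assemble_linear(strat, trials_by_speed)
                    if key not in cache:
                        cache[key] = fit_linear(Xtr, Ytr)
                    pred = cache[key].predict(Xte)
                    true = Yte
                else:
                    tr, va, te = assemble(strat, frames_by_speed)
                    if key not in cache:
                        model = build_model(
                            spec_factory(family, N), seed=train_config.seed
                        )
                        train(model, (tr.inputs, tr.targets),
                              (va.inputs, va.targets), train_config)
                        cache[key] = model
                    pred = predict(cache[key], te.inputs)
                    true = te.targets
                if y_scaler is not None:
                    pred = y_scaler.inverse(pred.T).T
                    true = y_scaler.inverse(true.T).T
                m = metrics(true, pred)
                for ci, ch in enumerate(TARGET_NAMES):
                    rows.append({
                        "participant": pid,
                        "foot": foot,
                        "strategy": strat.name,
                        "speed": strat.speed if strat.speed is not None else "all",
                        "family": family,
                        "channel": ch,
                        "mae": float(m["mae"][ci]),
                        "rmse": float(m["rmse"][ci]),
                        "r2": float(m["r2"][ci]),
                        "n_test": len(true),
                    })
    return pd.DataFrame(rows)
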