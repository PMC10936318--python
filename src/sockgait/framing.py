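"""Sliding-window framing of aligned trials into supervised samples.

Each sample is a sequence-to-point pair: a contiguous window of N timesteps
over the 12 feature channels, labelled with the two target angles at the
window's final timestep.  The window slides by one timestep, so a contiguous
segment of length T yields max(0, T - N + 1) samples.  Windows never span a
QC-excision gap or a trial boundary, and each sample inherits the split
partition of its target timestep (a window straddling a split boundary
therefore belongs to the later partition, keeping training leak-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError

PARTITIONS = ("train", "val", "test")


@dataclass
class FrameDataset:
    """Windowed samples: inputs (M, 12, N), targets (M, 2)."""

    inputs: np.ndarray
    targets: np.ndarray
    origin: np.ndarray       # (M, 2): trial id, end-timestep of each window
    partition: np.ndarray    # (M,) int8 index into PARTITIONS
    N: int

    def __len__(self) -> int:
        return len(self.inputs)

    def subset(self, name: str) -> "FrameDataset":
        if name not in PARTITIONS:
            raise ConfigError(f"unknown partition {name!r}")
        m = self.partition == PARTITIONS.index(name)
        return FrameDataset(
            self.inputs[m], self.targets[m], self.origin[m], self.partition[m], self.N
        )

    @staticmethod
    def concat(datasets) -> "FrameDataset":
        datasets = list(datasets)
        if not datasets:
            raise ConfigError("cannot concatenate zero datasets")
        Ns = {d.N for d in datasets}
        if len(Ns) != 1:
            raise ConfigError("datasets have mixed window lengths")
        return FrameDataset(
            np.concatenate([d.inputs for d in datasets]),
            np.concatenate([d.targets for d in datasets]),
            np.concatenate([d.origin for d in datasets]),
            np.concatenate([d.partition for d in datasets]),
            Ns.pop(),
        )


def _empty(N: int, C: int) -> FrameDataset:
    return FrameDataset(
        np.empty((0, C, N)), np.empty((0, 2)), np.empty((0, 2), dtype=np.int64),
        np.empty((0,), dtype=np.int8), N,
    )


def make_frames(
    features: np.ndarray,
    targets: np.ndarray,
    N: int,
    segments=None,
    split: dict | None = None,
    trial_id: int = 0,
) -> FrameDataset:
    """Window a trial (or one of its segments) into a :class:`FrameDataset`.

    ``features`` is (C, T), ``targets`` (2, T).  ``segments`` restricts the
    windows to contiguous spans (default: the whole trial); a segment shorter
    than N yields no samples.  ``split`` maps partition name -> (start, end)
    timestep range; each sample takes the partition of its end timestep.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if N < 1:
        raise ConfigError("window length N must be >= 1")
    C, T = features.shape
    if targets.shape[1] != T:
        raise ConfigError("features and targets must share length")
    if segments is None:
        segments = [(0, T)]

    boundaries = None
    if split is not None:
        boundaries = np.array([split["train"][1], split["val"][1]])

    parts = []
    for s, e in segments:
        if e - s < N:
            continue
        win = sliding_window_view(features[:, s:e], N, axis=1)  # (C, m, N)
        win = np.ascontiguousarray(np.swapaxes(win, 0, 1))      # (m, C, N)
        ends = np.arange(s + N - 1, e)
        tgt = targets[:, ends].T
        if boundaries is not None:
            part = np.searchsorted(boundaries, ends, side="right").astype(np.int8)
        else:
            part = np.zeros(len(ends), dtype=np.int8)
        origin = np.stack([np.full(len(ends), trial_id, dtype=np.int64), ends], axis=1)
        parts.append(FrameDataset(win, tgt, origin, part, N))
    if not parts:
        return _empty(N, C)
    return FrameDataset.concat(parts)


def frames_from_trial(trial, N: int, trial_id: int = 0) -> FrameDataset:
    """Frame an :class:`~sockgait.prep.AlignedTrial` using its own segments/split."""
    return make_frames(
        trial.features, trial.targets, N,
        segments=trial.segments, split=trial.split, trial_id=trial_id,
    )


def window_search(
    trial,
    candidate_Ns,
    spec_factory,
    train_config,
    metrics_fn=None,
):
    """Evaluate a base model over candidate window lengths; pick the best.

    For each N: frame the trial, train ``spec_factory(N)`` with
    ``train_config``, and tabulate test MAE/RMSE/R2 (averaged over the two
    output channels).  Selection is the N with the lowest test MAE.  Returns
    ``(table, best_N)`` where ``table`` is a pandas DataFrame.
    """
    import pandas as pd

    from .estimators import build_model, predict, train
    from .evaluation import metrics as default_metrics

    metrics_fn = metrics_fn or default_metrics
    rows = []
    for N in candidate_Ns:
        frames = frames_from_trial(trial, N)
        tr, va, te = (frames.subset(p) for p in PARTITIONS)
        if min(len(tr), len(va), len(te)) == 0:
            raise ConfigError(f"window {N} leaves an empty partition")
        model = build_model(spec_factory(N), seed=train_config.seed)
        train(model, (tr.inputs, tr.targets), (va.inputs, va.targets), train_config)
        pred = predict(model, te.inputs)
        m = metrics_fn(te.targets, pred)
        rows.append({
            "N": N,
            "mae": float(np.mean(m["mae"])),
            "rmse": float(np.mean(m["rmse"])),
            "r2": float(np.mean(m["r2"])),
        })
    table = pd.DataFrame(rows)
    best_N = int(table.loc[table["mae"].idxmin(), "N"])
    return table, best_N
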