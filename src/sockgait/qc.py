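"""Outlier gait-cycle flagging and removal.

Quality control runs on the optical angle channels only.  Per channel, the
initial boundaries (IB) of a trial are the interval from the 25th percentile
of per-cycle minima to the 75th percentile of per-cycle maxima.  A scaled
bound "k IB" is that interval expanded about its midpoint by factor k (the
same half-width scaling as IQR fences), so 1.5/3/15 IB form a nested family.
A cycle is an outlier if, on either channel:

1. fluctuation — more than ``fluctuation_threshold`` large-amplitude sign
   alternations of the first difference occur at samples outside 1.5 IB
   (momentary tracking loss shows up as bursts of signal-range-sized
   alternating swings; an alternation counts only when the adjacent
   sample-to-sample jumps are at least the 1.5 IB half-width, which keeps
   ordinary measurement jitter on an out-of-band cycle from masquerading as
   fluctuation);
2. excursion — more than 10% of samples fall outside 3 IB, or any sample
   falls outside 15 IB;
3. mean shift — the cycle mean lies outside 3 IB.

The first criterion to fire is recorded, with mean shift checked before the
excursion clause: a wholesale shift necessarily also pushes most samples
beyond 3 IB, so checking the mean first is what keeps the two signatures
distinguishable.
Flagged cycles are excised from features and targets together so the streams
stay co-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError, EmptyTrialError

CRITERIA = ("fluctuation", "excursion", "mean_shift")


@dataclass(frozen=True)
class IntervalBounds:
    """Per-channel [lower, upper] fence in channel units (degrees)."""

    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ConfigError("lower bound exceeds upper bound")

    def scale(self, k: float) -> "IntervalBounds":
        """Expand about the midpoint by factor ``k`` (half-width scaling)."""
        mid = 0.5 * (self.lower + self.upper)
        half = 0.5 * (self.upper - self.lower) * k
        return IntervalBounds(mid - half, mid + half)

    def outside(self, x) -> np.ndarray:
        x = np.asarray(x)
        return (x < self.lower) | (x > self.upper)


def compute_ib(cycles, channel: np.ndarray) -> IntervalBounds:
    """Initial boundaries of one channel over a trial's cycles.

    Lower bound: 25th percentile of the per-cycle minima; upper bound: 75th
    percentile of the per-cycle maxima (linear-interpolation quantiles).
    """
    if not cycles:
        raise DegenerateInputError("compute_ib needs at least one cycle")
    channel = np.asarray(channel, dtype=float)
    mins = np.array([channel[c.start:c.end].min() for c in cycles])
    maxs = np.array([channel[c.start:c.end].max() for c in cycles])
    return IntervalBounds(
        float(np.percentile(mins, 25.0)), float(np.percentile(maxs, 75.0))
    )


def flag_cycle(cycle, targets: np.ndarray, ibs: dict, fluctuation_threshold: int = 5):
    """QC verdict for one cycle: ``(qc_status, qc_criterion)``.

    ``targets`` is the (2, T) optical matrix of the cycle's own trial and
    ``ibs`` maps channel name -> that trial's :class:`IntervalBounds`.
    """
    names = list(ibs)
    segs = {n: targets[i, cycle.start:cycle.end] for i, n in enumerate(names)}

    for n in names:
        x = segs[n]
        if len(x) < 3:
            continue
        b15 = ibs[n].scale(1.5)
        out15 = b15.outside(x)
        half15 = 0.5 * (b15.upper - b15.lower)
        d = np.diff(x)
        flips = np.flatnonzero(d[1:] * d[:-1] < 0) + 1  # sample index of each flip
        big = np.minimum(np.abs(d[1:]), np.abs(d[:-1])) >= half15
        flips = flips[big[flips - 1]]
        if int(np.count_nonzero(out15[flips])) > fluctuation_threshold:
            return "outlier", "fluctuation"
    for n in names:
        if ibs[n].scale(3.0).outside(segs[n].mean()):
            return "outlier", "mean_shift"
    for n in names:
        x = segs[n]
        out3 = ibs[n].scale(3.0).outside(x)
        if out3.mean() > 0.10 or ibs[n].scale(15.0).outside(x).any():
            return "outlier", "excursion"
    return "clean", "none"


def flag_cycles(cycles, targets: np.ndarray, ibs: dict, fluctuation_threshold: int = 5):
    """Apply :func:`flag_cycle` in place to every cycle; returns the list."""
    for c in cycles:
        c.qc_status, c.qc_criterion = flag_cycle(
            c, targets, ibs, fluctuation_threshold
        )
    return cycles


def filter_trial(streams: dict, cycles):
    """Excise flagged cycles from every stream; recompute cycles and segments.

    ``streams`` maps name -> (C, T) array; the cycles must partition [0, T)
    contiguously (a prefix-trimmed trial).  Returns
    ``(filtered_streams, kept_cycles, segments)`` where ``segments`` lists
    the contiguous spans of the filtered timeline (a span boundary wherever
    one or more cycles were removed).  Removing zero cycles is the identity,
    and the operation is idempotent.
    """
    T = {v.shape[-1] for v in streams.values()}
    if len(T) != 1:
        raise ConfigError("streams must share one length")
    T = T.pop()
    if cycles:
        if cycles[0].start != 0 or cycles[-1].end != T or any(
            a.end != b.start for a, b in zip(cycles[:-1], cycles[1:])
        ):
            raise ConfigError("cycles must contiguously partition [0, T)")
    kept = [c for c in cycles if c.qc_status == "clean"]
    if cycles and not kept:
        raise EmptyTrialError("all cycles flagged as outliers")

    new_cycles = []
    segments = []
    pieces = []
    cursor = 0
    seg_start = 0
    prev_end_original = None
    for c in kept:
        if prev_end_original is not None and c.start != prev_end_original:
            segments.append((seg_start, cursor))
            seg_start = cursor
        pieces.append((c.start, c.end))
        new_cycles.append(
            type(c)(
                start=cursor,
                end=cursor + len(c),
                qc_status=c.qc_status,
                qc_criterion=c.qc_criterion,
            )
        )
        cursor += len(c)
        prev_end_original = c.end
    segments.append((seg_start, cursor))

    out = {}
    for name, arr in streams.items():
        if pieces:
            out[name] = np.concatenate([arr[..., a:b] for a, b in pieces], axis=-1)
        else:
            out[name] = arr.copy()
    if not pieces:
        segments = [(0, T)]
        new_cycles = []
    return out, new_cycles, segments
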