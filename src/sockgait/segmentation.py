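"""Heel-strike detection and gait-cycle partitioning.

Detection is a two-step adaptive-threshold scheme on the raw (unsmoothed)
heel-pressure channel.  The steepest pressure rise of a step happens between
initial heel contact and foot-flat, so Step 1 finds local maxima of the first
difference exceeding a high percentile of that difference series, pruned by a
refractory gap shorter than any plausible cycle.  Step 2 walks backward from
each rise to the pressure onset: the last sample at or below a low percentile
of the channel.  Both thresholds are percentiles of the trial's own data, so
detection is invariant to the (arbitrary) pressure units and to offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError, DegenerateInputError


@dataclass
class GaitCycle:
    """Half-open interval [start, end) between consecutive heel strikes."""

    start: int
    end: int
    qc_status: str = "clean"
    qc_criterion: str = "none"

    def __len__(self) -> int:
        return self.end - self.start


def detect_heel_strikes(
    heel: np.ndarray,
    deriv_percentile: float = 99.0,
    neighborhood: int = 50,
    onset_percentile: float = 25.0,
    refractory: int = 100,
) -> np.ndarray:
    """Heel-strike indices from a heel-pressure channel.

    Parameters
    ----------
    heel:
        Pressure channel at 250 Hz (any units; thresholds are percentiles).
    deriv_percentile:
        Step 1 threshold: candidate rises are local maxima of the first
        difference at or above this percentile of the difference series.  The
        pressure rise of a step occupies only ~1-2% of samples, so the
        default keeps genuine rises while rejecting noise maxima.
    neighborhood:
        Step 2 backward search width in samples (default 0.2 s).
    onset_percentile:
        Pressure-onset threshold: the heel strike is the last sample at or
        below this percentile of the channel before the rise.
    refractory:
        Minimum gap between candidate rises, samples (default 0.4 s, shorter
        than the fastest plausible cycle).

    Returns a strictly increasing index array; a constant channel yields an
    empty result.
    """
    heel = np.asarray(heel, dtype=float)
    if not (0 < deriv_percentile < 100 and 0 < onset_percentile < 100):
        raise ConfigError("percentiles must lie in (0, 100)")
    if neighborhood >= len(heel):
        raise DegenerateInputError("neighborhood must be smaller than the channel")
    if np.ptp(heel) == 0:
        return np.array([], dtype=np.int64)

    d = np.diff(heel)
    height = np.percentile(d, deriv_percentile)
    peaks, _ = find_peaks(d, height=height, distance=max(1, int(refractory)))
    if len(peaks) == 0:
        return np.array([], dtype=np.int64)

    onset_level = np.percentile(heel, onset_percentile)
    strikes = []
    for p in peaks:
        w0 = max(0, p - int(neighborhood))
        window = heel[w0:p + 1]
        below = np.flatnonzero(window <= onset_level)
        if below.size:
            strikes.append(w0 + int(below[-1]))
        else:
            strikes.append(w0 + int(np.argmin(window)))
    return np.unique(np.asarray(strikes, dtype=np.int64))


def partition_cycles(heel_strikes: np.ndarray, T: int) -> list:
    """One :class:`GaitCycle` per consecutive heel-strike pair.

    Samples before the first and after the last heel strike belong to no
    cycle.  Fewer than two strikes give an empty list.
    """
    hs = np.asarray(heel_strikes, dtype=np.int64)
    if len(hs) and (np.any(np.diff(hs) <= 0) or hs[0] < 0 or hs[-1] > T):
        raise ConfigError("heel strikes must be strictly increasing within [0, T]")
    return [GaitCycle(int(a), int(b)) for a, b in zip(hs[:-1], hs[1:])]


def match_events(detected, truth, tol: int):
    """Greedy one-to-one event matching within ``tol`` samples.

    Returns ``(precision, recall)``; empty inputs give 0 for the affected
    score (1.0 precision when nothing was detected and nothing was true).
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if len(detected) == 0 and len(truth) == 0:
        return 1.0, 1.0
    used = np.zeros(len(truth), dtype=bool)
    hits = 0
    for d in detected:
        if len(truth) == 0:
            break
        err = np.abs(truth - d)
        err[used] = tol + 1
        j = int(np.argmin(err))
        if err[j] <= tol:
            used[j] = True
            hits += 1
    precision = hits / len(detected) if len(detected) else 0.0
    recall = hits / len(truth) if len(truth) else 0.0
    return precision, recall
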