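"""Rate reconciliation, stream alignment, smoothing, features, normalization.

The sock channels (125 Hz) are upsampled by linear interpolation to the
optical 250 Hz rate, the two streams are time-aligned by maximising the
normalized cross-correlation between the sock PFX channel and the optical FLX
channel (the toe-stand at the start of a trial gives both a large common
excursion), and the aligned streams are smoothed with a Savitzky-Golay filter
(window 31, polynomial order 5).  The model inputs are twelve channels: the
four smoothed stretch channels plus their first and second discrete
derivatives (central differences, one-sided at the ends).  Channels are
z-scored with statistics fitted on the training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import AlignmentUndefinedError, ConfigError, DegenerateInputError

STRETCH = ("PFX", "DFX", "INV", "EVR")
FEATURE_NAMES = tuple(
    [*STRETCH, *(f"d1_{c}" for c in STRETCH), *(f"d2_{c}" for c in STRETCH)]
)
TARGET_NAMES = ("FLX", "INV")


def upsample_linear(x: np.ndarray) -> np.ndarray:
    """Upsample a 125 Hz channel to 250 Hz by midpoint insertion.

    Output has length ``2 L``: original samples sit at even indices, inserted
    samples are the arithmetic midpoints of their neighbours, and the final
    sample is held once so the output matches the 250 Hz stream length.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DegenerateInputError("upsample_linear needs a 1-D channel of length >= 2")
    out = np.empty(2 * len(x), dtype=float)
    out[0::2] = x
    out[1:-1:2] = 0.5 * (x[:-1] + x[1:])
    out[-1] = x[-1]
    return out


def estimate_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> int:
    """Signed lag (samples) of stream ``b`` relative to stream ``a``.

    Returns the lag in ``[-max_lag, +max_lag]`` maximising the magnitude of
    the normalized cross-correlation between the overlapping parts of the two
    channels; positive lag means ``b`` trails ``a``.  Magnitude is used
    because the two aligned channels may be anticorrelated (plantarflexion
    drives PFX capacitance up while the optical FLX angle goes down).

    Raises
    ------
    AlignmentUndefinedError
        If either channel has zero variance.
    DegenerateInputError
        If ``max_lag`` is not smaller than both channel lengths.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    max_lag = int(max_lag)
    if max_lag < 0 or max_lag >= len(a) or max_lag >= len(b):
        raise DegenerateInputError("max_lag must be smaller than both channels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AlignmentUndefinedError("cannot align a constant channel")

    L = min(len(a), len(b))
    a = a[:L]
    b = b[:L]
    best_lag, best_rho = 0, -np.inf
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            aa, bb = a[: L - k], b[k:]
        else:
            aa, bb = a[-k:], b[: L + k]
        sa = aa.std()
        sb = bb.std()
        if sa == 0 or sb == 0:
            continue
        rho = abs(np.dot(aa - aa.mean(), bb - bb.mean()) / (len(aa) * sa * sb))
        if rho > best_rho:
            best_rho, best_lag = rho, k
    return best_lag


def apply_lag(channels_a: dict, channels_b: dict, lag: int):
    """Co-index two channel dictionaries given the lag of ``b`` behind ``a``.

    For positive lag the tail of every ``a`` channel and the head of every
    ``b`` channel are trimmed (and symmetrically for negative lag), so both
    streams come out with equal length ``L - |lag|`` and a relative shift of
    ``-lag``.  Returns ``(a_out, b_out, a_start)`` where ``a_start`` is the
    number of samples dropped from the head of the ``a`` timeline (needed to
    remap indices defined on it).
    """
    lag = int(lag)
    lengths = {len(v) for v in channels_a.values()} | {len(v) for v in channels_b.values()}
    if len(lengths) != 1:
        raise ConfigError("all channels must share one length before alignment")
    L = lengths.pop()
    if abs(lag) >= L:
        raise DegenerateInputError(f"|lag|={abs(lag)} >= stream length {L}")
    if lag >= 0:
        a_out = {k: v[: L - lag].copy() for k, v in channels_a.items()}
        b_out = {k: v[lag:].copy() for k, v in channels_b.items()}
        a_start = 0
    else:
        a_out = {k: v[-lag:].copy() for k, v in channels_a.items()}
        b_out = {k: v[: L + lag].copy() for k, v in channels_b.items()}
        a_start = -lag
    return a_out, b_out, a_start


def sg_smooth(x: np.ndarray, window: int = 31, polyorder: int = 5) -> np.ndarray:
    """Savitzky-Golay smoothing (defaults: window 31, order 5).

    Interior samples are the centre values of local degree-``polyorder``
    least-squares fits; at the edges the nearest full window's polynomial is
    evaluated instead of mirroring data (``mode="interp"``), so no samples
    are fabricated beyond the trial.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window <= 0:
        raise ConfigError("window must be odd and positive")
    if polyorder >= window:
        raise ConfigError("polyorder must be < window")
    if x.shape[-1] < window:
        raise DegenerateInputError(f"channel shorter than window {window}")
    return savgol_filter(x, window, polyorder, axis=-1, mode="interp")


def derivative_features(stretch: np.ndarray) -> np.ndarray:
    """Stack the 4 stretch channels with their first and second derivatives.

    Input is the smoothed ``(4, T)`` stretch matrix; output is ``(12, T)``
    with rows 0-3 the channels, 4-7 first derivatives and 8-11 second
    derivatives (units per sample).  Derivatives are central differences with
    one-sided differences at the boundaries.
    """
    stretch = np.asarray(stretch, dtype=float)
    if stretch.ndim != 2 or stretch.shape[0] != 4 or stretch.shape[1] < 3:
        raise DegenerateInputError("expected a (4, T>=3) stretch matrix")
    d1 = np.gradient(stretch, axis=1)
    d2 = np.gradient(d1, axis=1)
    return np.vstack([stretch, d1, d2])


@dataclass
class ChannelScaler:
    """Per-channel z-score transform fitted on training data only."""

    mean: np.ndarray
    sd: np.ndarray
    names: tuple

    @classmethod
    def fit(cls, arrays, names):
        """Fit on a list of ``(C, T_i)`` arrays (train portions, concatenated)."""
        cat = np.concatenate([np.asarray(a, dtype=float) for a in arrays], axis=1)
        if cat.shape[1] == 0:
            raise DegenerateInputError("empty training range for normalization")
        mean = cat.mean(axis=1)
        sd = cat.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            bad = ", ".join(names[i] for i in dead)
            raise ConfigError(f"zero-variance channel(s): {bad}")
        return cls(mean=mean, sd=sd, names=tuple(names))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean[:, None]) / self.sd[:, None]

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.sd[:, None] + self.mean[:, None]


def split_ranges(T: int, fractions=(0.6, 0.2, 0.2)) -> dict:
    """Contiguous train/val/test index ranges covering ``[0, T)`` in order."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    if len(fractions) == 2:
        fractions = (fractions[0], 0.0, fractions[1])
    t1 = int(T * fractions[0])
    t2 = int(T * (fractions[0] + fractions[1]))
    return {"train": (0, t1), "val": (t1, t2), "test": (t2, T)}


@dataclass
class AlignedTrial:
    """Lag-corrected 250 Hz trial: 12-channel features, 2-channel targets.

    ``features``/``targets``/``heel`` share length T.  ``segments`` lists the
    contiguous time spans remaining after outlier-cycle excision (windows must
    not straddle them); ``split`` holds the contiguous train/val/test ranges.
    """

    rate: int
    features: np.ndarray   # (12, T), smoothed stretch + derivatives
    targets: np.ndarray    # (2, T), FLX/INV degrees (smoothed)
    heel: np.ndarray       # (T,), unsmoothed pressure
    lag_applied: int
    split: dict
    segments: list
    participant_id: str = ""
    foot: str = "left"
    speed: float = float("nan")
    cycles: list = field(default_factory=list)
    truth_hs: np.ndarray | None = None
    truth_cycle_labels: list | None = None
    prefilter_cycles: list = field(default_factory=list)
    normalized: bool = False

    @property
    def T(self) -> int:
        return self.features.shape[1]


def preprocess_trial(
    trial,
    *,
    max_lag_s: float = 4.0,
    lag_override: int | None = None,
    run_qc: bool = True,
    sg_window: int = 31,
    sg_polyorder: int = 5,
    split=(0.6, 0.2, 0.2),
    detector_kwargs: dict | None = None,
    qc_kwargs: dict | None = None,
) -> AlignedTrial:
    """Full preparation of one raw trial into an (un-normalized) AlignedTrial.

    Steps: upsample the sock channels to 250 Hz; estimate the inter-system
    lag from PFX vs FLX (or take ``lag_override`` for trials without a usable
    toe-stand); co-index the streams; detect heel strikes on the unsmoothed
    pressure channel; trim to the [first, last) heel-strike span; flag and
    excise outlier cycles based on the optical channels; smooth; build the
    12-channel derivative features; attach contiguous split ranges.
    Normalization is a separate, per-participant step
    (:func:`normalize_trials`).
    """
    from . import qc as qc_mod
    from . import segmentation as seg_mod

    srs250 = {name: upsample_linear(trial.srs[name]) for name in trial.srs}
    if lag_override is not None:
        lag = int(lag_override)
    else:
        max_lag = int(round(max_lag_s * trial.mocap_rate))
        lag = estimate_lag(srs250["PFX"], trial.mocap["FLX"], max_lag)
    srs_al, mocap_al, a_start = apply_lag(srs250, trial.mocap, lag)

    heel = srs_al["HEEL"]
    hs = seg_mod.detect_heel_strikes(heel, **(detector_kwargs or {}))
    if len(hs) < 2:
        raise DegenerateInputError("fewer than two heel strikes detected")

    # Trim every stream to the [first HS, last HS) span; cycles partition it.
    lo, hi = int(hs[0]), int(hs[-1])
    stretch = np.vstack([srs_al[c][lo:hi] for c in STRETCH])
    targets = np.vstack([mocap_al[c][lo:hi] for c in TARGET_NAMES])
    heel = heel[lo:hi]
    cycles = seg_mod.partition_cycles(hs - lo, hi - lo)

    truth_hs = None
    truth_labels = None
    if getattr(trial, "truth", None) is not None:
        th = trial.truth.hs_indices - a_start - lo
        truth_hs = th[(th >= 0) & (th < hi - lo)]
        truth_labels = list(trial.truth.cycle_labels)

    segments = [(0, hi - lo)]
    prefilter = []
    if run_qc:
        ibs = {
            name: qc_mod.compute_ib(cycles, targets[i])
            for i, name in enumerate(TARGET_NAMES)
        }
        qc_mod.flag_cycles(cycles, targets, ibs, **(qc_kwargs or {}))
        prefilter = [
            type(c)(c.start, c.end, c.qc_status, c.qc_criterion) for c in cycles
        ]
        streams = {"stretch": stretch, "targets": targets, "heel": heel[None, :]}
        streams, cycles, segments = qc_mod.filter_trial(streams, cycles)
        stretch = streams["stretch"]
        targets = streams["targets"]
        heel = streams["heel"][0]

    stretch_s = np.vstack([
        _smooth_segments(stretch[i], segments, sg_window, sg_polyorder)
        for i in range(stretch.shape[0])
    ])
    targets_s = np.vstack([
        _smooth_segments(targets[i], segments, sg_window, sg_polyorder)
        for i in range(targets.shape[0])
    ])
    features = derivative_features(stretch_s)

    return AlignedTrial(
        rate=trial.mocap_rate,
        features=features,
        targets=targets_s,
        heel=heel,
        lag_applied=lag,
        split=split_ranges(features.shape[1], split),
        segments=segments,
        participant_id=trial.participant_id,
        foot=trial.foot,
        speed=trial.speed,
        cycles=cycles,
        truth_hs=truth_hs,
        truth_cycle_labels=truth_labels,
        prefilter_cycles=prefilter,
    )


def _smooth_segments(x, segments, window, polyorder):
    """Smooth each contiguous segment separately so excision joints don't bleed."""
    out = np.array(x, dtype=float)
    for s, e in segments:
        if e - s >= window:
            out[s:e] = sg_smooth(x[s:e], window, polyorder)
    return out


def normalize_trials(trials: list, scaler_pair=None):
    """Z-score all of a participant's trials from their pooled train ranges.

    Fits one feature scaler and one target scaler on the concatenated train
    portions of every trial, applies both to the full length of each trial,
    and returns ``(trials, (feature_scaler, target_scaler))``.  Pass
    ``scaler_pair`` to re-apply an existing fit instead.
    """
    if scaler_pair is None:
        f_parts = [t.features[:, slice(*t.split["train"])] for t in trials]
        y_parts = [t.targets[:, slice(*t.split["train"])] for t in trials]
        f_scaler = ChannelScaler.fit(f_parts, FEATURE_NAMES)
        y_scaler = ChannelScaler.fit(y_parts, TARGET_NAMES)
    else:
        f_scaler, y_scaler = scaler_pair
    for t in trials:
        if t.normalized:
            raise ConfigError("trial already normalized")
        t.features = f_scaler.transform(t.features)
        t.targets = y_scaler.transform(t.targets)
        t.normalized = True
    return trials, (f_scaler, y_scaler)
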