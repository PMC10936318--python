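"""Seeded simulation of dual-rate smart-sock walking trials.

A trial couples two recording systems:

* the sock: four capacitive stretch channels (PFX, DFX, INV, EVR) and one
  heel-pressure channel, sampled at 125 Hz;
* optical capture: sagittal (FLX) and frontal (INV) ankle angles in degrees,
  sampled at 250 Hz, delayed relative to the sock by an unknown integer lag.

The latent ankle-angle trajectories are quasi-periodic sums of phase-locked
sinusoidal harmonics with per-cycle amplitude jitter; cycle duration follows a
speed-dependent cadence model.  Stretch capacitance is a monotone
(parallel-plate) function of the corresponding angle half-wave: PFX stretches
under plantarflexion (negative FLX), DFX under dorsiflexion, and the INV/EVR
pair under positive/negative frontal angle.  Heel pressure rises sharply
(saturating exponential) at every heel strike, plateaus during stance and
decays at toe-off, so the steepest within-cycle rise marks the true heel
strike by construction.  A toe-stand manoeuvre near the start of the trial
produces the large synchronised excursion in PFX and FLX that downstream
cross-correlation alignment keys on.

Every random draw flows from ``config.seed`` through a single generator in a
fixed order (speed, cycle durations, amplitude jitters, channel noise), so
identical configurations reproduce trials bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    MOCAP_CHANNELS,
    OUTLIER_MECHANISMS,
    SELF_SELECTED,
    SRS_CHANNELS,
    SyntheticConfig,
)
from .errors import ConfigError, DegenerateInputError

# Harmonic amplitudes (degrees) and phases of the latent angle waveforms.
_FLX_AMPS = (9.0, 3.5, 1.5)
_FLX_PHASES = (0.0, 1.0, 2.2)
_INV_AMPS = (4.5, 1.8, 0.9)
_INV_PHASES = (0.7, 2.1, 4.0)

_STANCE_FRAC = 0.62      # fraction of the cycle with the heel loaded
_HEEL_TAU = 0.008        # s, time constant of the pressure rise at heel strike
_HEEL_DECAY_FRAC = 0.12  # fraction of the cycle over which pressure decays at toe-off
_STAND_LEVEL = 0.4       # heel pressure during quiet standing (walking plateau = 1)

_LINEAR_STRAIN_PER_DEG = 0.004
_SAT_STRAIN_MAX = 0.12
_SAT_THETA = 8.0  # degrees; the saturating response bends hard by ~2*theta


@dataclass
class TrialTruth:
    """Ground-truth labels of a synthetic trial (sock-timeline indices, 250 Hz)."""

    hs_indices: np.ndarray
    lag: int
    speed: float
    cycle_labels: list = field(default_factory=list)
    latent: dict | None = None

    def n_cycles(self) -> int:
        return max(0, len(self.hs_indices) - 1)


@dataclass
class TrialRecording:
    """One walking trial: raw sock channels at 125 Hz plus optical angles at 250 Hz."""

    participant_id: str
    foot: str
    speed: float
    srs: dict            # PFX, DFX, INV, EVR, HEEL -> (n125,) arrays
    mocap: dict          # FLX, INV -> (n250,) arrays, delayed by truth.lag
    srs_rate: int = 125
    mocap_rate: int = 250
    truth: TrialTruth | None = None

    def copy(self) -> "TrialRecording":
        truth = None
        if self.truth is not None:
            truth = TrialTruth(
                hs_indices=self.truth.hs_indices.copy(),
                lag=self.truth.lag,
                speed=self.truth.speed,
                cycle_labels=list(self.truth.cycle_labels),
                latent=None
                if self.truth.latent is None
                else {k: v.copy() for k, v in self.truth.latent.items()},
            )
        return TrialRecording(
            participant_id=self.participant_id,
            foot=self.foot,
            speed=self.speed,
            srs={k: v.copy() for k, v in self.srs.items()},
            mocap={k: v.copy() for k, v in self.mocap.items()},
            srs_rate=self.srs_rate,
            mocap_rate=self.mocap_rate,
            truth=truth,
        )


def _smoothstep(x):
    """C1 ramp: 0 below 0, 1 above 1, 3x^2-2x^3 between."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _waveform(phase, amps, phases):
    """Zero-anchored harmonic sum: f(0) = f(1) = 0 for cycle continuity."""
    out = np.zeros_like(phase)
    offset = 0.0
    for m, (a, p) in enumerate(zip(amps, phases), start=1):
        out += a * np.sin(2.0 * np.pi * m * phase + p)
        offset += a * np.sin(p)
    return out - offset


def _strain(halfwave, angle_map):
    if angle_map == "linear":
        return _LINEAR_STRAIN_PER_DEG * halfwave
    return _SAT_STRAIN_MAX * np.tanh(halfwave / _SAT_THETA)


def simulate_trial(config: SyntheticConfig) -> TrialRecording:
    """Simulate one walking trial from a :class:`SyntheticConfig`.

    Raises
    ------
    DegenerateInputError
        If ``duration`` cannot hold the toe-stand plus at least two gait cycles.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.mocap_rate
    n250 = int(round(config.duration * fs))
    n125 = n250 // 2

    if config.speed == SELF_SELECTED:
        speed = float(np.clip(0.89 + 0.05 * rng.standard_normal(), 0.74, 1.04))
    else:
        speed = float(config.speed)

    toe = config.toe_stand
    walk_start = toe.onset + toe.duration + 1.0
    mean_d = config.cadence_model.mean_cycle_duration(speed)
    if config.duration < walk_start + 2.0 * mean_d:
        raise DegenerateInputError(
            f"duration {config.duration}s too short for toe-stand plus two "
            f"{mean_d:.2f}s cycles"
        )

    # Heel-strike schedule on the 125 Hz grid (even 250 Hz indices), so the
    # pressure onset survives the 2x linear upsampling exactly.
    jitter = config.cadence_model.jitter_sd
    times = []
    t = walk_start
    while t < config.duration - 0.05:
        times.append(round(t * config.srs_rate) / config.srs_rate)
        t += max(0.5 * mean_d, mean_d + jitter * rng.standard_normal())
    hs_idx = np.array([int(round(ti * config.srs_rate)) * 2 for ti in times], dtype=np.int64)
    if len(hs_idx) < 2:
        raise DegenerateInputError("fewer than two heel strikes in trial")

    # Latent angles on an extended sock timeline so the lagged optical stream
    # can be carved out without edge effects.
    pad = max(abs(int(config.lag)), 8) + 8
    n_ext = n250 + 2 * pad
    t_ext = (np.arange(n_ext) - pad) / fs

    flx = np.zeros(n_ext)
    inv = np.zeros(n_ext)

    in_toe = (t_ext >= toe.onset) & (t_ext < toe.onset + toe.duration)
    flx[in_toe] -= toe.amplitude * np.sin(
        np.pi * (t_ext[in_toe] - toe.onset) / toe.duration
    ) ** 2

    boundaries = list(np.asarray(times)) + [times[-1] + mean_d]
    for k in range(len(boundaries) - 1):
        b0, b1 = boundaries[k], boundaries[k + 1]
        jf = 1.0 + config.amp_jitter * rng.standard_normal()
        ji = 1.0 + config.amp_jitter * rng.standard_normal()
        mask = (t_ext >= b0) & (t_ext < b1)
        if not mask.any():
            continue
        phase = (t_ext[mask] - b0) / (b1 - b0)
        flx[mask] = jf * _waveform(phase, _FLX_AMPS, _FLX_PHASES)
        inv[mask] = ji * _waveform(phase, _INV_AMPS, _INV_PHASES)

    flx_srs = flx[pad:pad + n250]
    inv_srs = inv[pad:pad + n250]

    # Heel pressure on the 125 Hz grid.
    t125 = np.arange(n125) / config.srs_rate
    stand = _smoothstep((t125 - 0.1) / 0.8)
    stand *= 1.0 - _smoothstep((t125 - (toe.onset - 0.3)) / 0.3)
    stand += _smoothstep((t125 - (toe.onset + toe.duration)) / 0.3) * (
        1.0 - _smoothstep((t125 - (walk_start - 0.7)) / 0.6)
    )
    heel = _STAND_LEVEL * stand
    heel[t125 >= walk_start - 0.05] = 0.0
    for k in range(len(boundaries) - 1):
        b0, b1 = boundaries[k], boundaries[k + 1]
        cd = b1 - b0
        toe_off = b0 + _STANCE_FRAC * cd
        dlen = _HEEL_DECAY_FRAC * cd
        mask = (t125 >= b0) & (t125 < min(b1, config.duration))
        if not mask.any():
            continue
        tc = t125[mask]
        p = np.zeros_like(tc)
        rising = tc < toe_off
        p[rising] = 1.0 - np.exp(-(tc[rising] - b0) / _HEEL_TAU)
        decaying = (tc >= toe_off) & (tc < toe_off + dlen)
        p_off = 1.0 - np.exp(-_STANCE_FRAC * cd / _HEEL_TAU)
        p[decaying] = p_off * (1.0 - _smoothstep((tc[decaying] - toe_off) / dlen))
        heel[mask] = p

    even = np.s_[0:n250:2]
    clean_srs = {
        "PFX": config.sensor_geometry.capacitance(
            _strain(np.maximum(-flx_srs[even], 0.0), config.angle_map)
        ),
        "DFX": config.sensor_geometry.capacitance(
            _strain(np.maximum(flx_srs[even], 0.0), config.angle_map)
        ),
        "INV": config.sensor_geometry.capacitance(
            _strain(np.maximum(inv_srs[even], 0.0), config.angle_map)
        ),
        "EVR": config.sensor_geometry.capacitance(
            _strain(np.maximum(-inv_srs[even], 0.0), config.angle_map)
        ),
        "HEEL": heel,
    }
    lag = int(config.lag)
    clean_mocap = {
        "FLX": flx[pad - lag:pad - lag + n250].copy(),
        "INV": inv[pad - lag:pad - lag + n250].copy(),
    }

    def _noise_sd(stream, name, clean):
        if config.noise_sd is not None:
            key = f"{stream}:{name}"
            if key in config.noise_sd:
                return float(config.noise_sd[key])
        if config.noise_frac > 0:
            return config.noise_frac * float(np.std(clean))
        return 0.0

    srs = {}
    for name in SRS_CHANNELS:
        sd = _noise_sd("srs", name, clean_srs[name])
        x = clean_srs[name] + (sd * rng.standard_normal(n125) if sd > 0 else 0.0)
        if name == "HEEL":
            x = np.maximum(x, 0.0)
        srs[name] = x
    mocap = {}
    for name in MOCAP_CHANNELS:
        sd = _noise_sd("mocap", name, clean_mocap[name])
        mocap[name] = clean_mocap[name] + (
            sd * rng.standard_normal(n250) if sd > 0 else 0.0
        )

    truth = TrialTruth(
        hs_indices=hs_idx,
        lag=lag,
        speed=speed,
        cycle_labels=["none"] * max(0, len(hs_idx) - 1),
        latent={"FLX": flx_srs, "INV": inv_srs},
    )
    trial = TrialRecording(
        participant_id=config.participant_id,
        foot=config.foot,
        speed=speed,
        srs=srs,
        mocap=mocap,
        srs_rate=config.srs_rate,
        mocap_rate=config.mocap_rate,
        truth=truth,
    )
    if any(r > 0 for r in config.outlier_rates.values()):
        trial = inject_outlier_cycles(trial, config.outlier_rates, seed=config.seed + 1)
    return trial


def inject_outlier_cycles(
    trial: TrialRecording, rates: dict, seed: int | None = None
) -> TrialRecording:
    """Corrupt a random subset of gait cycles in the optical channels.

    Each selected cycle suffers exactly one mechanism, drawn per cycle with
    the given probabilities (mechanisms are mutually exclusive):

    * ``fluctuation`` — a burst of large alternating sample-to-sample swings,
      the signature of momentary marker-tracking loss;
    * ``excursion`` — a short block of samples pushed far outside the normal
      range, or occasionally a single extreme spike;
    * ``mean_shift`` — the whole cycle offset by a constant.

    The per-cycle selection consumes exactly ``truth.n_cycles()`` uniform
    draws up front (in cycle order), so the corrupted-cycle count can be
    reproduced by replaying the same seeded generator.

    Raises
    ------
    ConfigError
        If any rate is outside [0, 1] or the rates sum beyond 1.
    DegenerateInputError
        If the trial carries no ground-truth heel strikes.
    """
    for mech, rate in rates.items():
        if mech not in OUTLIER_MECHANISMS:
            raise ConfigError(f"unknown outlier mechanism {mech!r}")
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"outlier rate for {mech!r} outside [0, 1]")
    if sum(rates.values()) > 1.0 + 1e-12:
        raise ConfigError("outlier rates must sum to <= 1")
    if trial.truth is None or len(trial.truth.hs_indices) < 2:
        raise DegenerateInputError("trial has no ground-truth heel strikes")

    out = trial.copy()
    n_cycles = out.truth.n_cycles()
    rng = np.random.default_rng(seed)
    u = rng.random(n_cycles)

    # per-channel scale of the walking signal, for corruption magnitudes
    hs = out.truth.hs_indices
    lag = out.truth.lag
    n = len(out.mocap["FLX"])
    stats = {}
    for name in MOCAP_CHANNELS:
        lo_i = int(np.clip(hs[0] + lag, 0, n))
        hi_i = int(np.clip(hs[-1] + lag, 0, n))
        seg = out.mocap[name][lo_i:hi_i]
        lo, hi = np.percentile(seg, [1.0, 99.0])
        stats[name] = ((hi + lo) / 2.0, max((hi - lo) / 2.0, 1e-9))

    ordered = list(OUTLIER_MECHANISMS)
    for k in range(n_cycles):
        cum = 0.0
        mech = "none"
        for m in ordered:
            cum += rates.get(m, 0.0)
            if u[k] < cum:
                mech = m
                break
        if mech == "none":
            continue
        s = int(np.clip(hs[k] + lag, 0, n))
        e = int(np.clip(hs[k + 1] + lag, 0, n))
        length = e - s
        if length < 12:
            continue
        channel = str(rng.choice(MOCAP_CHANNELS))
        mid, hw = stats[channel]
        sign = float(rng.choice([-1.0, 1.0]))
        x = out.mocap[channel]
        if mech == "fluctuation":
            burst = max(6, int(0.08 * length))
            start = s + int(rng.integers(length // 4, length // 2))
            idx = np.arange(start, min(start + burst, e))
            signs = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0) * sign
            x[idx] = mid + 2.2 * hw * signs
        elif mech == "excursion":
            if rng.random() < 0.7:
                block = int(0.12 * length) + 1
                start = s + int(rng.integers(0, length - block))
                x[start:start + block] = mid + sign * 4.0 * hw
            else:
                pos = s + int(rng.integers(0, length))
                x[pos] = mid + sign * 20.0 * hw
        else:  # mean_shift
            x[s:e] += sign * 4.5 * hw
        out.truth.cycle_labels[k] = mech
    return out


def write_trial(trial: TrialRecording, outdir) -> dict:
    """Write a trial as two CSV streams plus a JSON ground-truth sidecar.

    Returns the mapping of stream name to written path.  The latent angle
    trajectories are not serialised (they are regenerable from the config).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{trial.participant_id}_{trial.foot}_{trial.speed:.2f}"
    n125 = len(trial.srs["HEEL"])
    n250 = len(trial.mocap["FLX"])
    srs_df = pd.DataFrame({"time_s": np.arange(n125) / trial.srs_rate}
                          | {k: trial.srs[k] for k in SRS_CHANNELS})
    mocap_df = pd.DataFrame({"time_s": np.arange(n250) / trial.mocap_rate}
                            | {k: trial.mocap[k] for k in MOCAP_CHANNELS})
    paths = {
        "srs": outdir / f"{stem}_srs.csv",
        "mocap": outdir / f"{stem}_mocap.csv",
        "truth": outdir / f"{stem}_truth.json",
    }
    srs_df.to_csv(paths["srs"], index=False)
    mocap_df.to_csv(paths["mocap"], index=False)
    if trial.truth is not None:
        payload = {
            "hs_indices": trial.truth.hs_indices.tolist(),
            "lag": trial.truth.lag,
            "speed": trial.truth.speed,
            "cycle_labels": trial.truth.cycle_labels,
        }
        paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_trial(outdir, participant_id: str, foot: str, speed: float) -> TrialRecording:
    """Read a trial written by :func:`write_trial` (latent angles excluded)."""
    outdir = Path(outdir)
    stem = f"{participant_id}_{foot}_{speed:.2f}"
    srs_df = pd.read_csv(outdir / f"{stem}_srs.csv")
    mocap_df = pd.read_csv(outdir / f"{stem}_mocap.csv")
    truth = None
    truth_path = outdir / f"{stem}_truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = TrialTruth(
            hs_indices=np.asarray(payload["hs_indices"], dtype=np.int64),
            lag=int(payload["lag"]),
            speed=float(payload["speed"]),
            cycle_labels=list(payload["cycle_labels"]),
        )
    return TrialRecording(
        participant_id=participant_id,
        foot=foot,
        speed=speed,
        srs={k: srs_df[k].to_numpy() for k in SRS_CHANNELS},
        mocap={k: mocap_df[k].to_numpy() for k in MOCAP_CHANNELS},
        truth=truth,
    )
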