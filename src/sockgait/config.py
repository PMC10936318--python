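"""Configuration objects for the synthetic walking-trial generator.

The generator emulates a treadmill protocol in which a participant wearing an
instrumented sock (four capacitive stretch sensors across the ankle plus one
heel pressure sensor, sampled at 125 Hz) walks while an optical motion-capture
system records sagittal (FLX) and frontal (INV) ankle angles in degrees at
250 Hz.  A brief toe-stand at the start of every trial serves as the
synchronisation landmark between the two recording systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigError

#: The four treadmill belt speeds used in the walking protocol (m/s).
PROTOCOL_SPEEDS = (0.67, 0.89, 1.12, 1.34)

#: Label for the participant-chosen comfortable speed (drawn near 0.89 m/s).
SELF_SELECTED = "self-selected"

STRETCH_CHANNELS = ("PFX", "DFX", "INV", "EVR")
SRS_CHANNELS = STRETCH_CHANNELS + ("HEEL",)
MOCAP_CHANNELS = ("FLX", "INV")

OUTLIER_MECHANISMS = ("fluctuation", "excursion", "mean_shift")


@dataclass(frozen=True)
class CadenceModel:
    """Walking-speed → gait-cycle-duration model.

    Cycle (stride) duration shortens linearly with belt speed; successive
    cycles jitter around the mean with ``jitter_sd``.

    Parameters
    ----------
    intercept, slope:
        Mean cycle duration is ``intercept - slope * speed`` seconds.  The
        defaults give ~1.56 s at 0.67 m/s down to ~1.23 s at 1.34 m/s, in the
        range typical of slow-to-brisk treadmill walking.
    jitter_sd:
        Cycle-to-cycle standard deviation of the duration, seconds.
    """

    intercept: float = 1.90
    slope: float = 0.50
    jitter_sd: float = 0.02

    def mean_cycle_duration(self, speed: float) -> float:
        d = self.intercept - self.slope * speed
        if d <= 0:
            raise ConfigError(f"cadence model gives non-positive duration at {speed} m/s")
        return d


@dataclass(frozen=True)
class SensorGeometry:
    """Parallel-plate geometry of one capacitive stretch sensor.

    Capacitance is ``C = eps0 * eps_r * A / d`` with the overlap area ``A``
    growing proportionally with strain, so capacitance is an affine, strictly
    increasing function of stretch.  Values are reported in picofarads.
    """

    epsilon_0: float = 8.854e-12  # F/m
    epsilon_r: float = 3.2        # silicone dielectric
    area: float = 4.0e-4          # m^2, unstretched electrode overlap
    thickness: float = 5.0e-4     # m, dielectric layer

    def capacitance(self, strain):
        """Capacitance in pF at fractional ``strain`` (0 = unstretched)."""
        return 1e12 * self.epsilon_0 * self.epsilon_r * self.area * (1.0 + strain) / self.thickness


@dataclass(frozen=True)
class ToeStand:
    """The toe-stand synchronisation manoeuvre at the start of a trial."""

    onset: float = 1.0      # s after recording start
    duration: float = 2.0   # s
    amplitude: float = 25.0  # degrees of plantarflexion at the peak


def default_outlier_rates() -> dict:
    return {m: 0.0 for m in OUTLIER_MECHANISMS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one simulated walking trial.

    Parameters
    ----------
    speed:
        Belt speed in m/s, or ``"self-selected"`` for a participant-specific
        comfortable speed drawn near 0.89 m/s.
    duration:
        Trial length in seconds (protocol default: 3 min).
    lag:
        Inter-system delay injected into the optical stream, in integer
        250 Hz samples.  Positive means the optical stream trails the sock.
    noise_frac:
        Measurement-noise standard deviation per channel as a fraction of
        that channel's clean signal standard deviation.  Explicit per-channel
        values (channel units) may be given in ``noise_sd`` instead and take
        precedence.
    angle_map:
        ``"linear"`` makes sensor strain proportional to the angle half-wave;
        ``"saturating"`` uses a tanh compression, a deliberately nonlinear
        sensor response.
    amp_jitter:
        Fractional per-cycle amplitude jitter of the latent angle waveforms.
    """

    speed: float | str = 0.89
    duration: float = 180.0
    seed: int = 0
    srs_rate: int = 125
    mocap_rate: int = 250
    lag: int = 0
    noise_frac: float = 0.0
    noise_sd: dict | None = None
    cadence_model: CadenceModel = field(default_factory=CadenceModel)
    outlier_rates: dict = field(default_factory=default_outlier_rates)
    sensor_geometry: SensorGeometry = field(default_factory=SensorGeometry)
    toe_stand: ToeStand = field(default_factory=ToeStand)
    angle_map: str = "linear"
    amp_jitter: float = 0.05
    participant_id: str = "P01"
    foot: str = "left"

    def __post_init__(self):
        if self.srs_rate * 2 != self.mocap_rate:
            raise ConfigError("srs_rate x 2 must equal mocap_rate")
        if self.duration <= 0 or self.srs_rate <= 0:
            raise ConfigError("duration and rates must be positive")
        if self.noise_frac < 0:
            raise ConfigError("noise_frac must be >= 0")
        if self.noise_sd is not None and any(v < 0 for v in self.noise_sd.values()):
            raise ConfigError("noise_sd values must be >= 0")
        for mech, rate in self.outlier_rates.items():
            if mech not in OUTLIER_MECHANISMS:
                raise ConfigError(f"unknown outlier mechanism {mech!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"outlier rate for {mech!r} outside [0, 1]")
        if sum(self.outlier_rates.values()) > 1.0 + 1e-12:
            raise ConfigError("outlier rates must sum to <= 1")
        if self.angle_map not in ("linear", "saturating"):
            raise ConfigError(f"unknown angle_map {self.angle_map!r}")
        if self.foot not in ("left", "right"):
            raise ConfigError("foot must be 'left' or 'right'")
        if isinstance(self.speed, str) and self.speed != SELF_SELECTED:
            raise ConfigError(f"speed must be numeric or {SELF_SELECTED!r}")
        if not isinstance(self.speed, str) and self.speed <= 0:
            raise ConfigError("speed must be positive")
        # cadence must shorten with speed over the protocol range
        fast = self.cadence_model.mean_cycle_duration(PROTOCOL_SPEEDS[-1])
        slow = self.cadence_model.mean_cycle_duration(PROTOCOL_SPEEDS[0])
        if not fast < slow:
            raise ConfigError("cadence model must shorten cycles as speed increases")

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
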