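# Methods

This note records the models, the numerical choices, and the reasoning
behind the places where the design was genuinely open.  It documents what
the code does; every number quoted here is computed by the tests or by
`scripts/acceptance.py`, not asserted from elsewhere.

## The synthetic trial generator

The generator (`sockgait.synthetic`) emulates a treadmill protocol: the
participant stands, rises briefly onto their toes (the synchronisation
landmark), and then walks at a fixed belt speed while two systems record —
a sock with four capacitive stretch sensors and a heel pressure sensor at
125 Hz, and an optical system producing sagittal (FLX) and frontal (INV)
ankle angles in degrees at 250 Hz, delayed by an unknown integer lag.

**Latent angles.**  Each gait cycle maps phase φ ∈ [0,1) through a fixed
three-harmonic sum per channel, anchored so the waveform is zero at both
cycle boundaries (continuity regardless of per-cycle amplitude jitter,
default 5%).  Peak-to-peak amplitudes are ~±10–14° (FLX) and ~±6° (INV),
in the range of treadmill ankle kinematics.  No musculoskeletal model is
implied: the waveform is a statistical stand-in that is smooth, periodic,
speed-parameterisable and exactly known.

**Cadence.**  Mean cycle duration is `1.90 − 0.50·v` seconds at belt speed
`v` m/s (≈1.56 s at 0.67 m/s to ≈1.23 s at 1.34 m/s, typical of slow-to-
brisk walking), with 0.02 s cycle-to-cycle jitter.  Heel-strike times are
quantised to the 125 Hz grid so the pressure onset survives the 2×
upsampling exactly.  The self-selected speed is a participant draw near
0.89 m/s.

**Sensor map.**  Stretch sensors respond to half-waves of the corresponding
angle (PFX to plantarflexion, DFX to dorsiflexion, INV/EVR to the frontal
half-waves), through strain into parallel-plate capacitance
C = ε₀ε_r·A(strain)/d, reported in pF.  Two response shapes are available:
`linear` (strain ∝ angle, making the angle an exact linear combination of
two channels — the ground truth for regression-recovery checks) and
`saturating` (strain ∝ tanh(angle/8°), a deliberately nonlinear response
that linear regression cannot invert — the task used for the capacity-
ordering checks).

**Heel pressure.**  Within each cycle the pressure rises as a saturating
exponential (τ = 8 ms) that is exactly zero at the true heel strike,
plateaus through stance (62% of the cycle), and decays smoothly at
toe-off; swing is zero.  This makes the steepest within-cycle rise, and the
pressure onset, land on the true strike by construction.  Standing-phase
pressure transitions are deliberately gentle (≥0.3 s) so they never
compete with heel-strike rises.  Units are arbitrary; the detector is
scale- and offset-invariant, so nothing downstream depends on them.

**Noise and outliers.**  Per-channel Gaussian noise is specified as a
fraction of each channel's clean standard deviation (default condition in
tests: 5%); heel pressure is clipped at zero.  Outlier cycles are injected
into the optical channels only, one mechanism per selected cycle:
alternating ±2.2·half-width swing bursts (fluctuation), 12%-of-cycle blocks
at 4·half-width or single spikes at 20·half-width (excursion), or a
whole-cycle ±4.5·half-width offset (mean shift).  Magnitudes are chosen to
sit decisively on the outlier side of the 1.5/3/15 fences while leaving the
trial-level bounds (robust quartiles) essentially unchanged at realistic
rates.  The per-cycle selection consumes its uniform draws up front, in
cycle order, so counts are replayable from the seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: soft-tissue artefact, sensor drift and
hysteresis, creep in the sock's fit, non-integer and drifting inter-system
lag, marker-occlusion patterns that correlate with gait phase, and between-
participant anatomical variation.  Results on synthetic trials validate the
pipeline's mechanics, not the hardware.

## Preprocessing

* **Upsampling** inserts arithmetic midpoints and holds the final sample
  once, so a 125 Hz channel of length L becomes exactly 2L samples and
  matches the 250 Hz stream; original samples sit at even indices.
* **Lag estimation** maximises |ρ(k)| over k ∈ [−max_lag, +max_lag]
  (default ±4 s) where ρ is the normalized cross-correlation of the
  overlapping parts of sock PFX and optical FLX.  The magnitude is used
  because plantarflexion drives PFX capacitance up while FLX goes down.
  Constant channels raise an alignment-undefined error.  Trials whose
  recordings miss the toe-stand take an explicit `lag_override` instead.
* **Savitzky–Golay** smoothing uses window 31, polynomial order 5; edges
  evaluate the nearest full window's polynomial (`mode="interp"`) rather
  than mirroring, so no data are fabricated at the trial boundaries where
  the toe-stand lives.
* **Derivatives** are central differences (one-sided at the ends), units
  per sample.  Feature order is fixed: 4 smoothed stretch channels, then
  first, then second derivatives.
* **Normalization** is per participant: one z-transform per channel fitted
  on the concatenated training ranges of all of that participant's trials,
  applied to the full length of each, inverse-applied to predictions before
  reporting degrees.
* **Splits** are contiguous and ordered train→val→test (60/20/20;
  regression uses the first 80% = train+val for fitting and the last 20%
  for testing, with no validation set).

## Heel-strike detection

The two-step adaptive scheme exposes four tunables: `deriv_percentile`
(99), `onset_percentile` (25), `neighborhood` (0.2 s), `refractory`
(0.4 s, shorter than any plausible cycle at 1.34 m/s).  The derivative
percentile is high because a step's pressure rise occupies only ~1–2% of
samples: a threshold at the 90th percentile of the difference series would
by construction sit below ~10% of noise samples and admit spurious
candidates, while the 99th keeps every true rise (their peaks occupy the
extreme tail) and rejects noise maxima at all simulated noise levels.
Detection runs on the aligned but unsmoothed pressure channel — smoothing
would blunt precisely the rise that step 1 keys on.  Both thresholds are
percentiles of the trial's own data, making detection invariant to scale
and offset of the (unit-less) pressure channel.

## Cycle QC

"k IB" is read as the IB interval expanded about its midpoint by factor k
(half-width scaling, as in IQR fences) — the only reading under which
1.5/3/15 form a nested family.  Quantiles use linear interpolation.  IB is
computed per optical channel over all cycles of a trial.

Criteria are evaluated fluctuation → mean-shift → excursion, recording the
first to fire.  The mean test precedes the excursion test because a
wholesale shift necessarily also pushes most samples beyond 3 IB; checking
the mean first is what keeps the two signatures distinguishable.  The
fluctuation criterion counts first-difference sign alternations at samples
outside 1.5 IB, but only alternations whose adjacent jumps are at least the
1.5 IB half-width: tracking loss produces signal-range-sized swings, and
without the amplitude gate ordinary measurement jitter on any out-of-band
cycle would register as fluctuation.  The threshold is >5 such alternations
per cycle (config-exposed).

QC reads only the optical channels; flagged cycles are excised from sock
and optical streams together, and the excision boundaries are carried as
"segments" so that no sliding window ever spans a gap.

## Framing and estimators

Windows are sequence-to-point: N timesteps of the 12 features, labelled
with the two angles at the window's final timestep, stride 1.  Each sample
inherits the split partition of its target timestep, so a boundary-
straddling window belongs to the later partition and never trains on its
own test information.  The window search trains a base model per candidate
N and selects the lowest test MAE.

The linear family solves the normal equations exactly on instantaneous
12-vectors plus intercept; rank deficiency is diagnosed by pivoted QR and
reported with the collinear channel names.

The deep families run on a small NumPy engine (`sockgait.nn`: LSTM,
time-axis convolution with (k,1) kernels, (2,1) max-pooling, dense,
inverted dropout; Glorot initialisation, forget-gate bias 1, manual
backpropagation verified against central finite differences to ~1e-8).
Training follows the fixed regime: Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), mean
absolute error, 40 epochs, batch 128, learning rate decaying linearly
0.05→0.04 (the schedule shape was open; linear is the simplest monotone
choice matching the stated endpoints), parameters checkpointed at the
minimum validation MAE.  One seed governs initialisation, shuffling and
dropout; reproducibility is bitwise per device.

The base CNN's activations default to LeakyReLU (slope 0.2), which sits in
the architecture search space alongside ReLU: under the aggressive 0.05
starting rate the first Adam steps are large enough to drive every plain
ReLU unit negative, after which the network is frozen at the mean predictor
(observed as a validation MAE pinned at E|N(0,1)| ≈ 0.80 on standardized
targets).  LeakyReLU keeps gradient flowing through the transient and the
net then settles within ~20 epochs.

## Evaluation

MAE and RMSE are reported in degrees after inverse normalization; R² is
1 − SSE/SST about the true mean, computed per channel on the concatenated
test timesteps (not per cycle).  The three strategy designs share the
framing machinery: speed-specific uses one trial's own split; multi-speed
pools every speed's ranges; speed-independent trains like multi-speed and
tests on one speed.  Multi-speed and speed-independent models over the same
trial set are therefore fitted once and reused.  Reports are long-format
(one row per participant × strategy × speed × family × channel), weighted
per trial; aggregation across participants is left to the caller.

When comparing per-speed and pooled test MAEs, sampling standard errors are
estimated from 1 s block means of the absolute errors: timestep errors on
smoothed quasi-periodic signals are strongly autocorrelated, and a
per-sample standard error would be a severe underestimate.

## Problem sizes

Tests and the acceptance script run reduced-scale versions of the full
protocol, chosen as the smallest sizes at which each property is stable:
12 s trials for the ±100-sample lag sweeps, 40 s trials (10 seeds × 5
speeds) for detection scores, two 150 s trials (~200 cycles) for QC rates,
and a 48 s saturating-sensor trial framed at N = 40 (~6.5k training
windows) for the family-ordering comparison, with the 40-epoch regime
intact.  The full-protocol sizes (3-minute trials, N = 60–100) run through
the same code paths and remain configurable.

## Known limitations

* The engine is CPU-only and unbatched across models; the full five-speed,
  ten-participant, three-family study at full scale is hours, not minutes.
* Linear-interpolation upsampling and integer-sample lags are exact for the
  generator's conventions; fractional or drifting lag is out of scope.
* The fluctuation criterion's amplitude gate is a calibrated
  operationalization of a qualitative symptom; on real recordings its
  threshold (and all QC scalings) should be revisited against labelled
  artefacts.
* Interparticipant (transfer) models are explicitly out of scope.
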