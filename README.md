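# sockgait

Joint-angle estimation from a smart-sock wearable, end to end: simulate (or
load) dual-rate walking trials, align the sock and optical-capture streams,
detect heel strikes, reject outlier gait cycles, and train joint-angle
estimators — for researchers validating stretch-sensor wearables against
optical motion capture.

## The problem

An instrumented sock carries four capacitive stretch sensors across the
ankle — plantarflexion (PFX), dorsiflexion (DFX), inversion (INV), eversion
(EVR) — plus a heel pressure sensor, sampled at 125 Hz.  An optical capture
system records the sagittal (FLX) and frontal (INV) ankle angles in degrees
at 250 Hz.  The analysis question: how accurately can the sock's capacitance
signals reproduce the optically measured joint angles during treadmill
walking at 0.67–1.34 m/s, and do models trained at one speed generalize to
others?

## The pipeline

1. **Rate reconciliation & alignment.**  Sock channels are upsampled 2× by
   linear interpolation; the unknown inter-system delay is the lag
   maximizing the normalized cross-correlation |ρ(k)| between sock PFX and
   optical FLX (a toe-stand at trial start gives both a large common
   excursion).  Streams are then co-indexed and trimmed.
2. **Heel-strike segmentation.**  A two-step adaptive-threshold detector:
   candidate rises are local maxima of the heel-pressure first difference
   above a high percentile of that series; each candidate is traced backward
   to the pressure onset (last sample at or below a low percentile of the
   channel).  Cycles are the half-open intervals between consecutive strikes.
3. **Cycle QC.**  Per optical channel, the initial boundaries IB =
   [Q₀.₂₅(per-cycle minima), Q₀.₇₅(per-cycle maxima)]; "k IB" expands the
   interval about its midpoint by factor k.  A cycle is an outlier on either
   channel if it shows a burst of large alternating swings outside 1.5 IB
   (tracking loss), >10% of samples beyond 3 IB or any sample beyond 15 IB
   (excursions), or a cycle mean beyond 3 IB (shift).  Flagged cycles are
   excised from features and targets together.
4. **Features & framing.**  Savitzky–Golay smoothing (window 31, order 5),
   then 12 features per timestep (4 stretch channels + first + second
   derivatives), z-scored with statistics from the training range only
   (contiguous 60/20/20 split; 80/20 for regression).  Sliding windows of N
   timesteps (stride 1) map to the two angles at the window's last timestep
   (sequence-to-point).
5. **Estimators.**  Multivariable linear regression (normal equations, per
   timestep); an LSTM (best variant: 64→32 units, dropout 0.2, dense 2); a
   CNN (50/50 conv, max-pool (2,1), 100/100 conv, dense 100 → 2, kernels
   (3,1) along time).  Deep models train 40 epochs with Adam on an MAE loss,
   the learning rate decaying 0.05→0.04, keeping the best-validation
   parameters.  Three strategy designs control train/test speeds:
   speed-specific, multi-speed, speed-independent.

The neural-network layer stack and its training loop are implemented in
NumPy with manual backpropagation (`sockgait.nn`) — small, inspectable, and
reproducible bit-for-bit under a seed on one device.

A seeded synthetic-trial generator (`sockgait.synthetic`) produces walking
trials with the statistical structure the pipeline assumes — quasi-periodic
latent angles with speed-dependent cadence, a parallel-plate capacitance
map C = ε₀ε_r·A/d from stretch to sensor reading, a sharp heel-pressure rise
at each true heel strike, an integer inter-system lag, per-channel noise and
injected outlier cycles — with ground truth for every downstream stage.

## Worked example

`examples/04_train_estimators.py` builds a 30 s trial whose sensors saturate
(tanh response), so the capacitance→angle map is genuinely nonlinear, and
trains all three families:

```
frames: train 3692, val 1240, test 1241 (12 x 30 each)
linear regression   test MAE 0.594 deg
LSTM (64/32 units)  test MAE 0.327 deg (best epoch 11)
CNN (50/50/100/100) test MAE 0.467 deg (best epoch 18)
```

MAE is in degrees of ankle angle on held-out timesteps.  The linear model is
pinned at the bias floor of the saturating sensor response; the windowed
deep models invert it, the LSTM most effectively.  The other examples cover
simulation (`01`), alignment (`02`, exact integer-lag recovery), heel-strike
detection and QC (`03`: 80/80 strikes, all 20 injected outlier cycles
flagged with the right criterion), and the strategy study (`05`).

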