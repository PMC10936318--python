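"""Run the preprocessing chain: upsample, align, segment, QC, smooth, split.

The inter-system lag is estimated by normalized cross-correlation between
the sock PFX channel and the optical FLX channel (the toe-stand gives both a
large common excursion), then streams are co-indexed, heel strikes detected,
outlier cycles removed, and the 12-channel feature matrix built.
"""

import sockgait as sg

cfg = sg.SyntheticConfig(speed=1.12, duration=60.0, seed=7, lag=-45,
                         noise_frac=0.05)
trial = sg.simulate_trial(cfg)
aligned = sg.preprocess_trial(trial)

print(f"injected lag: {trial.truth.lag} samples; "
      f"estimated lag: {aligned.lag_applied} samples")
print(f"aligned length: {aligned.T} samples at {aligned.rate} Hz")
print(f"features: {aligned.features.shape[0]} channels "
      "(4 stretch + 4 first derivatives + 4 second derivatives)")
print(f"gait cycles kept: {len(aligned.cycles)} "
      f"(flagged {sum(c.qc_status == 'outlier' for c in aligned.prefilter_cycles)})")
print("split ranges:", {k: v for k, v in aligned.split.items()})

# An exactly recovered lag means the two recording systems are co-indexed to
# the sample; the 60/20/20 split is contiguous in time to avoid leakage.
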