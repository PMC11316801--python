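"""Simulate a 5-day experiment bundle and inspect its ground truth.

Builds one synthetic mouse x field recording: trial schedules with
~74% correct behavior, drifting tuning amplitudes (per-variable time
constants tau), neuropil-contaminated fluorescence, and 30x30 um ROI
patches. Prints the trial-type counts and the ground-truth amplitude
decay, which downstream analyses will try to recover.
"""

import numpy as np

from driftdecode import TaskConfig, generate_experiment
from driftdecode.io import write_bundle

config = TaskConfig(n_trials=60, n_cells=40, n_days=5)
tau = {"context": 7.3, "motor": 1.9,
       "post_decision_outcome": 2.2, "post_trial_outcome": 35.7}
bundle = generate_experiment(config, tau, seed=42, n_unstable=4)

print(f"bundle: {bundle.n_days} days x {bundle.n_cells} cells, "
      f"{config.frames_per_day} frames/day at {config.frame_rate_hz:g} Hz")
for dd in bundle.days:
    counts = {tt: sum(t.trial_type == tt for t in dd.trials)
              for tt in ("CL", "IR", "IL", "CR", "aborted")}
    correct = counts["CL"] + counts["CR"]
    total = sum(counts.values()) - counts["aborted"]
    print(f"  day {dd.day}: {counts}  performance {correct / total:.2f}")

gt = bundle.ground_truth
tuned_ctx = gt.tuned[0][:, 0]
mean_amp = gt.amplitude[:, tuned_ctx, 0].mean(axis=1)
print("\nmean context amplitude by day (dF/F %):",
      np.round(mean_amp, 2))
print("expected decay factor e^((1-day)/7.3):",
      np.round(np.exp((1 - np.arange(1, 6)) / 7.3), 3))
print("-> tuned amplitudes decay exponentially; turnover re-tunes "
      f"{gt.turnover_prob:.0%} of cells per day.")

write_bundle(bundle, "scratch_bundle.h5")
print("\nwrote HDF5 bundle to scratch_bundle.h5 "
      "(groups /day{d}/f_soma, /day{d}/trials, ..., /ground_truth)")
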