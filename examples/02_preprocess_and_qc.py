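"""From raw fluorescence to QC-selected cells.

Runs the neuropil correction (alpha chosen per cell to decorrelate the
corrected trace from the neuropil), dF/F with F0 = mode of the density,
and the three inclusion gates: session behavior, activity reliability
(circular-shuffle null), and ROI morphological stability (SSIM vs a
random-window null).
"""

import numpy as np

from driftdecode import (TaskConfig, align_to_trials, check_session_inclusion,
                         generate_experiment, reliability_test,
                         roi_stability_test, sample_null_windows, select_cells)
from driftdecode.preprocess import preprocess_day
from driftdecode.task import CORRECT_TYPES

config = TaskConfig(n_trials=60, n_cells=30, n_days=3)
bundle = generate_experiment(config, {"context": 7.3, "motor": 1.9}, seed=1,
                             n_unstable=3)

n_days, n_cells = config.n_days, config.n_cells
reliable = np.zeros((n_days, n_cells), bool)
stable = np.ones((n_days, n_cells), bool)
included = np.zeros(n_days, bool)

for d_idx, dd in enumerate(bundle.days):
    si = check_session_inclusion(dd.trials)
    included[d_idx] = si.included
    print(f"day {dd.day}: min/type {si.min_count}, "
          f"performance {si.performance:.2f}, included={si.included}")

    dff, alphas = preprocess_day(dd.f_soma, dd.f_neuropil)
    tt = align_to_trials(dff, dd.trials, (0, 9), config.frame_rate_hz,
                         day=dd.day)
    correct = np.isin(tt.labels, list(CORRECT_TYPES))
    for c in range(n_cells):
        reliable[d_idx, c] = reliability_test(tt.values[c][correct],
                                              seed=100 * dd.day + c).reliable
    if d_idx == 0:
        print(f"  mean estimated alpha {alphas.mean():.3f} "
              f"(true contamination {config.neuropil_alpha_true})")
    print(f"  reliable cells: {int(reliable[d_idx].sum())}/{n_cells}")

p1 = bundle.days[0].roi_patches
for d_idx in range(1, n_days):
    dd = bundle.days[d_idx]
    for c in range(n_cells):
        nulls = sample_null_windows(dd.field, (dd.field.shape[0] // 2,) * 2,
                                    config.patch_size_px, 60, seed=c)
        stable[d_idx, c] = roi_stability_test(p1[c], dd.roi_patches[c],
                                              nulls).stable
    print(f"ROI-stable day 1 vs {dd.day}: {int(stable[d_idx].sum())}/{n_cells} "
          f"(generator relocated {int(bundle.unstable_cells.sum())})")

sel = select_cells(reliable, stable, included)
print("\nincluded cells per (day 1, day k) pair:",
      {k: v.size for k, v in sel.pairwise.items()},
      "| strict all-day set:", sel.strict.size)
print("-> these are the cells every cross-day comparison is restricted to.")
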