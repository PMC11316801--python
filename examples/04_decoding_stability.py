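"""Cross-day decoding and the NP decay time constant.

Trains per-timebin linear SVMs on day-1 population activity and tests
them on later days, integrates performance above chance over each
variable's 1.5-s window, normalizes by day 1 (NP), and fits
NP = e^((1-day)/tau). tau is the number of days until decoding above
chance falls to 1/e of its day-1 level — the stability metric.
"""

import numpy as np

from driftdecode import (TaskConfig, VARIABLES, align_to_trials,
                         decode_across_days, fit_decay, generate_experiment,
                         integrate_window, normalize_performance)
from driftdecode.preprocess import preprocess_day

config = TaskConfig(n_trials=60, n_cells=80, n_days=5, turnover_prob=0.0)
tau_true = {"context": 7.3, "motor": 1.9,
            "post_decision_outcome": 2.2, "post_trial_outcome": 35.7}
bundle = generate_experiment(config, tau_true, seed=12)

tensors = {}
for dd in bundle.days:
    dff, _ = preprocess_day(dd.f_soma, dd.f_neuropil)
    tensors[dd.day] = align_to_trials(dff, dd.trials, (0, 9),
                                      config.frame_rate_hz, day=dd.day)

fr = config.frame_rate_hz
for vname in ("context", "motor"):
    w0, w1 = VARIABLES[vname].window
    bins = np.arange(int(w0 * fr), int(w1 * fr) + 1)
    nps = {1: 1.0}
    print(f"\n{vname} (window {w0}-{w1} s, true tau {tau_true[vname]} d)")
    for day in range(2, 6):
        within = decode_across_days(tensors[1].values, tensors[1].labels,
                                    None, None, vname, n_iter=25,
                                    seed=day, bins=bins)
        cross = decode_across_days(tensors[1].values, tensors[1].labels,
                                   tensors[day].values, tensors[day].labels,
                                   vname, test_day=day, n_iter=25,
                                   seed=100 + day, bins=bins)
        a1 = integrate_window(within.mean_performance, within.bin_times,
                              (w0, w1))
        ak = integrate_window(cross.mean_performance, cross.bin_times,
                              (w0, w1))
        ratio, excluded = normalize_performance({1: a1, day: ak})
        if not excluded:
            nps[day] = ratio[day]
        print(f"  day {day}: within-day perf "
              f"{within.mean_performance.mean():.2f}, cross-day "
              f"{cross.mean_performance.mean():.2f}, NP "
              f"{nps.get(day, float('nan')):.2f}")
    fit = fit_decay(list(nps.values()), list(nps.keys()), "normalized")
    print(f"  fitted tau = {fit.tau:.1f} days "
          "(NP = 1 on the training day; 1/e one time constant later)")
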