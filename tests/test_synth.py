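"""Synthetic-world generator: schedule, tuning drift, activity, patches."""

import numpy as np
import pytest

from driftdecode import (TaskConfig, generate_trial_schedule, trial_type_of,
                         make_drifting_tuning, simulate_day_activity,
                         generate_roi_patches, generate_experiment,
                         check_session_inclusion, compute_ssi)
from driftdecode.synth import GroundTruthTuning, make_response_kernels
from driftdecode.task import CLASS_RULES, ConfigError, TRIAL_TYPES


class TestTrialSchedule:
    def test_records_satisfy_type_mapping_and_frame_layout(self):
        cfg = TaskConfig(n_trials=200, n_cells=5)
        sch = generate_trial_schedule(cfg, seed=0)
        assert len(sch) == 200
        prev_end = -1
        for tr in sch:
            assert tr.trial_type == trial_type_of(tr.context, tr.choice)
            assert tr.start_frame == prev_end + 1
            assert tr.start_frame < tr.decision_frame < tr.end_frame <= tr.reward_end_frame
            assert tr.reward_end_frame - tr.start_frame + 1 == cfg.trial_len_frames
            prev_end = tr.reward_end_frame

    def test_trial_count_conservation(self):
        cfg = TaskConfig(n_trials=300, n_cells=5, abort_rate=0.1)
        sch = generate_trial_schedule(cfg, seed=3)
        counts = {tt: sum(t.trial_type == tt for t in sch)
                  for tt in TRIAL_TYPES + ("aborted",)}
        assert sum(counts.values()) == 300
        assert counts["aborted"] > 0

    def test_anti_repeat_ramp_suppresses_context_repeats(self):
        cfg = TaskConfig(n_trials=10_000, n_cells=5, abort_rate=0.0)
        sch = generate_trial_schedule(cfg, seed=11)
        ctx = np.array([t.context for t in sch])
        repeat_frac = np.mean(ctx[1:] == ctx[:-1])
        # unconstrained i.i.d. contexts would repeat at rate 0.5
        assert repeat_frac < 0.5
        assert repeat_frac < 0.47  # ramp pushes it well below

    def test_realized_performance_matches_target(self):
        cfg = TaskConfig(n_trials=10_000, n_cells=5, abort_rate=0.0,
                         target_performance=0.74)
        sch = generate_trial_schedule(cfg, seed=2)
        correct = np.mean([t.outcome == "correct" for t in sch])
        assert abs(correct - 0.74) < 0.03

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            TaskConfig(n_trials=-1)
        with pytest.raises(ConfigError):
            TaskConfig(target_performance=0.3)
        with pytest.raises(ConfigError):
            TaskConfig(frame_rate_hz=float("nan"))


class TestDriftingTuning:
    def test_infinite_tau_freezes_amplitudes(self):
        cfg = TaskConfig(n_trials=10, n_cells=50, n_days=5, turnover_prob=0.0)
        tun = make_drifting_tuning(cfg, {}, seed=0)  # missing taus -> inf
        for d in range(1, 5):
            np.testing.assert_allclose(tun.amplitude[d], tun.amplitude[0])

    def test_unit_tau_decays_by_e_per_day(self):
        cfg = TaskConfig(n_trials=10, n_cells=50, n_days=3, turnover_prob=0.0)
        tau = {v: 1.0 for v in ("context", "motor", "post_decision_outcome",
                                "post_trial_outcome")}
        tun = make_drifting_tuning(cfg, tau, seed=1)
        tuned = tun.tuned[0]
        ratio = tun.amplitude[1][tuned] / tun.amplitude[0][tuned]
        np.testing.assert_allclose(ratio, np.exp(-1.0), rtol=1e-12)

    def test_log_amplitude_linear_in_day(self, tau_map):
        cfg = TaskConfig(n_trials=10, n_cells=30, n_days=5, turnover_prob=0.0)
        tun = make_drifting_tuning(cfg, tau_map, seed=4)
        days = np.arange(1, 6)
        for vi, v in enumerate(tun.variables):
            cells = np.nonzero(tun.tuned[0][:, vi] & (tun.amplitude[0][:, vi] > 0))[0]
            for c in cells[:5]:
                la = np.log(tun.amplitude[:, c, vi])
                slopes = np.diff(la) / np.diff(days)
                np.testing.assert_allclose(slopes, -1.0 / tau_map[v], rtol=1e-9)

    def test_turnover_retention_is_binomial(self):
        cfg = TaskConfig(n_trials=10, n_cells=1000, n_days=2, turnover_prob=0.2)
        tun = make_drifting_tuning(cfg, {}, seed=9)
        retained = int(tun.retained[1].sum())
        # ~800 expected, +/- 3 binomial s.d.
        sd = np.sqrt(1000 * 0.2 * 0.8)
        assert abs(retained - 800) <= 3 * sd

    def test_nonpositive_tau_rejected(self):
        cfg = TaskConfig(n_trials=10, n_cells=5)
        with pytest.raises(ConfigError):
            make_drifting_tuning(cfg, {"context": -2.0}, seed=0)


class TestSimulatedActivity:
    def _silent_world(self, **kw):
        return TaskConfig(n_trials=20, n_cells=4, n_days=1, noise_sd=0.0,
                          neuropil_alpha_true=0.0, trial_gain_sd=0.0,
                          tuned_fraction=0.0, abort_rate=0.0, **kw)

    def test_zero_amplitude_zero_noise_gives_constant_baseline(self):
        cfg = self._silent_world()
        tun = make_drifting_tuning(cfg, {}, seed=0)
        trials = generate_trial_schedule(cfg, seed=0)
        soma, _ = simulate_day_activity(tun, trials, cfg, day=1, seed=0)
        np.testing.assert_allclose(
            soma, np.broadcast_to(tun.baseline[:, None], soma.shape), rtol=1e-12)

    def test_class_difference_equals_amplitude_times_kernel(self):
        """Noiseless context cell: trial-mean class difference = A * kernel."""
        cfg = self._silent_world()
        trials = generate_trial_schedule(cfg, seed=1)
        kernels = make_response_kernels(cfg)
        amplitude = 10.0
        n_vars = 4
        tuned = np.zeros((1, 1, n_vars), bool); tuned[0, 0, 0] = True  # context
        pref = np.zeros((1, 1, n_vars), np.int8)                      # class 0
        amp = np.zeros((1, 1, n_vars)); amp[0, 0, 0] = amplitude
        tun = GroundTruthTuning(
            variables=("context", "motor", "post_decision_outcome",
                       "post_trial_outcome"),
            tuned=tuned, preferred=pref, amplitude=amp, tau={},
            kernels=kernels, baseline=np.array([100.0]), turnover_prob=0.0,
            retained=np.ones((1, 1), bool))
        soma, _ = simulate_day_activity(tun, trials, cfg, day=1, seed=0)
        dff = 100.0 * (soma[0] - 100.0) / 100.0
        tlen = cfg.trial_len_frames
        cls = np.array([CLASS_RULES["context"][t.trial_type] for t in trials])
        per_trial = dff.reshape(len(trials), tlen)
        diff = per_trial[cls == 0].mean(axis=0) - per_trial[cls == 1].mean(axis=0)
        np.testing.assert_allclose(diff, amplitude * kernels["context"],
                                   atol=1e-9)

    def test_alpha_recovery_from_contaminated_soma(self):
        """Population-mean alpha estimate recovers the injected 0.7 +/- 0.05.

        Per-cell estimates carry sampling noise from the autocorrelated
        neuropil (se ~ 0.1 at 5400 frames), so recovery is asserted on the
        mean over cells.
        """
        from driftdecode import estimate_alpha
        cfg = TaskConfig(n_trials=60, n_cells=25, n_days=1,
                         neuropil_alpha_true=0.7)
        tun = make_drifting_tuning(cfg, {}, seed=2)
        trials = generate_trial_schedule(cfg, seed=2)
        soma, neuropil = simulate_day_activity(tun, trials, cfg, day=1, seed=2)
        alphas = [estimate_alpha(soma[c], neuropil[c]) for c in range(25)]
        assert abs(np.mean(alphas) - 0.7) < 0.05


class TestRoiPatches:
    def test_zero_jitter_zero_noise_patches_identical(self):
        cfg = TaskConfig(n_trials=10, n_cells=6, n_days=3)
        patches, _, _, _ = generate_roi_patches(cfg, n_unstable=0, seed=0,
                                                jitter_px=0.0, noise_sd=0.0)
        for d in range(1, 3):
            np.testing.assert_array_equal(patches[d], patches[0])
        assert compute_ssi(patches[0, 0], patches[2, 0]) == 1.0

    def test_unstable_cells_change_content(self):
        cfg = TaskConfig(n_trials=10, n_cells=6, n_days=2)
        patches, _, _, unstable = generate_roi_patches(cfg, n_unstable=3, seed=1)
        assert unstable.sum() == 3
        for c in np.nonzero(unstable)[0]:
            assert compute_ssi(patches[0, c], patches[1, c]) < 0.9

    def test_too_many_unstable_rejected(self):
        cfg = TaskConfig(n_trials=10, n_cells=4, n_days=2)
        with pytest.raises(ConfigError):
            generate_roi_patches(cfg, n_unstable=5, seed=0)


class TestExperimentBundle:
    def test_same_seed_gives_identical_bundles(self, small_config, tau_map):
        b1 = generate_experiment(small_config, tau_map, seed=123)
        b2 = generate_experiment(small_config, tau_map, seed=123)
        for d1, d2 in zip(b1.days, b2.days):
            np.testing.assert_array_equal(d1.f_soma, d2.f_soma)
            np.testing.assert_array_equal(d1.roi_patches, d2.roi_patches)
            assert [t.trial_type for t in d1.trials] == \
                   [t.trial_type for t in d2.trials]

    def test_day_structure_and_inclusion(self, small_bundle, small_config):
        assert small_bundle.n_days == small_config.n_days
        cells = {dd.f_soma.shape[0] for dd in small_bundle.days}
        assert cells == {small_config.n_cells}
        for dd in small_bundle.days:
            assert check_session_inclusion(dd.trials).included

    def test_hdf5_roundtrip(self, small_bundle, tmp_path):
        from driftdecode.io import read_bundle, write_bundle
        path = str(tmp_path / "bundle.h5")
        write_bundle(small_bundle, path)
        back = read_bundle(path)
        assert back.n_days == small_bundle.n_days
        np.testing.assert_allclose(back.days[0].f_soma,
                                   small_bundle.days[0].f_soma, rtol=1e-6)
        assert [t.trial_type for t in back.days[1].trials] == \
               [t.trial_type for t in small_bundle.days[1].trials]
        np.testing.assert_array_equal(back.ground_truth.tuned,
                                      small_bundle.ground_truth.tuned)
        assert back.ground_truth.tau == small_bundle.ground_truth.tau
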