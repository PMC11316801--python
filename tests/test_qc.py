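"""Inclusion gates: session behavior, reliability, ROI stability."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from driftdecode import (TaskConfig, check_session_inclusion, compute_ssi,
                         generate_roi_patches, reliability_test,
                         roi_stability_test, sample_null_windows, select_cells)


def _reference_ssim(a, b):
    """Independent SSIM oracle: direct Wang et al. formula with a Gaussian
    window (sigma 1.5, truncate 3.5), dynamic range from the pooled pair."""
    a = a.astype(float); b = b.astype(float)
    dr = max(a.max(), b.max()) - min(a.min(), b.min())
    c1 = (0.01 * dr) ** 2
    c2 = (0.03 * dr) ** 2
    filt = dict(sigma=1.5, truncate=3.5, mode="nearest")
    mu_a = gaussian_filter(a, **filt)
    mu_b = gaussian_filter(b, **filt)
    e_aa = gaussian_filter(a * a, **filt)
    e_bb = gaussian_filter(b * b, **filt)
    e_ab = gaussian_filter(a * b, **filt)
    va = e_aa - mu_a ** 2
    vb = e_bb - mu_b ** 2
    cab = e_ab - mu_a * mu_b
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cab + c2)) / \
               ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2))
    pad = 5  # (win 11 - 1) // 2, the border skimage crops
    return float(ssim_map[pad:-pad, pad:-pad].mean())


class TestSessionInclusion:
    def test_example_session_with_minimum_seven(self):
        # 29 CL, 9 IR, 7 IL, 34 CR: lowest count 7, performance 63/79
        labels = ["CL"] * 29 + ["IR"] * 9 + ["IL"] * 7 + ["CR"] * 34
        si = check_session_inclusion(labels)
        assert si.min_count == 7
        assert si.performance == pytest.approx(63 / 79)
        assert si.included

    def test_equal_counts_fail_the_performance_gate(self):
        si = check_session_inclusion(["CL"] * 2 + ["IR"] * 2 + ["IL"] * 2 + ["CR"] * 2)
        assert si.min_count == 2 and si.performance == 0.5
        assert not si.included  # performance must be strictly > 0.5

    def test_single_trial_of_a_type_excludes(self):
        si = check_session_inclusion(["CL"] * 5 + ["IR"] * 5 + ["IL"] + ["CR"] * 5)
        assert si.min_count == 1
        assert not si.included

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            check_session_inclusion(["aborted", "aborted"])


class TestReliability:
    def test_identical_repeated_response_is_reliable(self):
        profile = np.sin(np.linspace(0, 3 * np.pi, 90)) + 1
        x = np.tile(profile, (12, 1))
        res = reliability_test(x, seed=0)
        assert res.cc_true == pytest.approx(1.0)
        assert res.reliable

    def test_constant_trace_is_degenerate_not_reliable(self):
        res = reliability_test(np.full((10, 90), 2.0), seed=0)
        assert res.degenerate and not res.reliable

    def test_null_rate_near_five_percent(self):
        rng = np.random.default_rng(42)
        flagged = sum(reliability_test(rng.standard_normal((20, 90)), seed=i).reliable
                      for i in range(300))
        # 95th-percentile criterion -> ~5% type-I; binomial 3 s.d. ~ 3.8%
        assert 0.01 <= flagged / 300 <= 0.09

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            reliability_test(np.zeros((3, 90)))


class TestSsi:
    def test_identical_patches(self):
        a = np.random.default_rng(0).random((30, 30))
        assert compute_ssi(a, a.copy()) == pytest.approx(1.0)

    def test_contrast_inversion_penalized(self):
        a = np.random.default_rng(1).random((30, 30))
        assert compute_ssi(a, a.max() - a) < 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a = gaussian_filter(rng.random((30, 30)), 1.0)
        b = gaussian_filter(rng.random((30, 30)), 1.0)
        assert compute_ssi(a, b) == pytest.approx(_reference_ssim(a, b), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_ssi(np.zeros((10, 10)), np.zeros((12, 12)))


@pytest.fixture(scope="module")
def patch_world():
    cfg = TaskConfig(n_trials=10, n_cells=40, n_days=2)
    patches, fields, centers, unstable = generate_roi_patches(
        cfg, n_unstable=20, seed=3)
    return cfg, patches, fields, centers, unstable


class TestRoiStability:
    def _run(self, patch_world, cells, metric="ssim"):
        cfg, patches, fields, centers, _ = patch_world
        flags = []
        for c in cells:
            nulls = sample_null_windows(fields[1], centers[c],
                                        cfg.patch_size_px, n_windows=60,
                                        seed=100 + c)
            res = roi_stability_test(patches[0, c], patches[1, c], nulls,
                                     metric=metric)
            flags.append(res.stable)
        return np.array(flags)

    def test_stable_cells_flagged_stable(self, patch_world):
        _, _, _, _, unstable = patch_world
        stable_cells = np.nonzero(~unstable)[0]
        flags = self._run(patch_world, stable_cells)
        assert flags.mean() >= 0.95

    def test_relocated_cells_flagged_unstable(self, patch_world):
        _, _, _, _, unstable = patch_world
        flags = self._run(patch_world, np.nonzero(unstable)[0])
        assert flags.mean() <= 0.10

    def test_metrics_agree_on_clear_cases(self, patch_world):
        _, _, _, _, unstable = patch_world
        cells = np.arange(len(unstable))
        agree = self._run(patch_world, cells, "ssim") == \
            self._run(patch_world, cells, "corr2d")
        assert agree.mean() >= 0.90

    def test_offset_invariance_of_decision(self, patch_world):
        cfg, patches, fields, centers, _ = patch_world
        c = 0
        nulls = sample_null_windows(fields[1], centers[c], cfg.patch_size_px,
                                    n_windows=60, seed=5)
        base = roi_stability_test(patches[0, c], patches[1, c], nulls)
        off = roi_stability_test(patches[0, c] + 50, patches[1, c] + 50,
                                 nulls + 50)
        assert base.stable == off.stable

    def test_too_few_null_windows_rejected(self):
        with pytest.raises(ValueError):
            roi_stability_test(np.zeros((10, 10)), np.zeros((10, 10)),
                               np.zeros((10, 10, 10)))


class TestSelectCells:
    def test_all_gates_pass_keeps_everything(self):
        rel = np.ones((3, 5), bool)
        stab = np.ones((3, 5), bool)
        sel = select_cells(rel, stab, np.ones(3, bool))
        for k in (2, 3):
            np.testing.assert_array_equal(sel.pairwise[k], np.arange(5))
        np.testing.assert_array_equal(sel.strict, np.arange(5))

    def test_day1_only_reliable_cell_excluded_everywhere(self):
        rel = np.zeros((3, 4), bool)
        rel[0, 0] = True          # reliable on day 1 only
        rel[:, 1] = True          # reliable throughout
        sel = select_cells(rel, np.ones((3, 4), bool), np.ones(3, bool))
        for k in (2, 3):
            assert 0 not in sel.pairwise[k]
            assert 1 in sel.pairwise[k]

    def test_strict_set_is_subset_of_every_pair(self):
        rng = np.random.default_rng(0)
        rel = rng.random((4, 30)) < 0.7
        stab = rng.random((4, 30)) < 0.8
        sel = select_cells(rel, stab, np.ones(4, bool))
        for k, cells in sel.pairwise.items():
            assert set(sel.strict).issubset(set(cells))

    def test_failed_session_empties_its_pairs(self):
        rel = np.ones((3, 5), bool)
        included = np.array([True, False, True])
        sel = select_cells(rel, np.ones((3, 5), bool), included)
        assert sel.pairwise[2].size == 0
        assert sel.pairwise[3].size == 5
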