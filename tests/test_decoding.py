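"""Per-timebin SVM decoding: labels, homogenization, curves, controls."""

import numpy as np
import pytest

from driftdecode import (VARIABLES, decode_across_days, homogenize_and_split,
                         pseudopopulation_decode, significant_encoding,
                         subsample_controls, variable_labels)
from driftdecode.decoding import DecodingCurve
from driftdecode.task import TRIAL_TYPES


class TestVariableLabels:
    def test_methods_enumeration(self):
        # CL: context 1, left choice, correct outcome
        assert variable_labels("CL", "context") == variable_labels("IR", "context")
        assert variable_labels("CL", "motor") == variable_labels("IL", "motor")
        assert variable_labels("CL", "post_decision_outcome") == \
            variable_labels("CR", "post_decision_outcome")
        assert variable_labels("IR", "post_decision_outcome") != \
            variable_labels("CL", "post_decision_outcome")

    def test_rules_are_distinct_partitions(self):
        parts = set()
        for v in ("context", "motor", "post_decision_outcome"):
            labels = tuple(variable_labels(t, v) for t in TRIAL_TYPES)
            canon = labels if labels[0] == 0 else tuple(1 - x for x in labels)
            parts.add(canon)
        assert len(parts) == 3

    def test_aborted_rejected(self):
        with pytest.raises(ValueError):
            variable_labels("aborted", "context")

    def test_windows_are_1p5_seconds(self):
        for spec in VARIABLES.values():
            assert spec.window[1] - spec.window[0] == pytest.approx(1.5)


class TestHomogenizeAndSplit:
    def _labels(self, counts):
        return np.concatenate([[tt] * n for tt, n in zip(TRIAL_TYPES, counts)])

    @pytest.mark.parametrize("counts", [(19, 7, 6, 23), (8, 8, 8, 8), (2, 2, 2, 2)])
    def test_disjoint_underlying_trials_and_equal_counts(self, counts):
        labels = self._labels(counts)
        rng = np.random.default_rng(0)
        target = min(counts)
        for _ in range(20):
            train, test = homogenize_and_split(labels, rng)
            assert len(train) == len(test) == 4 * target
            assert set(train).isdisjoint(set(test))
            for tt in TRIAL_TYPES:
                assert np.sum(labels[train] == tt) == target
                assert np.sum(labels[test] == tt) == target

    def test_type_below_two_rejected(self):
        labels = self._labels((5, 5, 1, 5))
        with pytest.raises(ValueError):
            homogenize_and_split(labels, np.random.default_rng(0))


def _make_data(rng, n_per, n_cells, n_bins, sep, var="context",
               info_bins=None):
    """Gaussian activity with a class separation on `info_bins`."""
    labels = np.concatenate([[tt] * n_per for tt in TRIAL_TYPES])
    x = rng.standard_normal((n_cells, 4 * n_per, n_bins))
    if sep:
        cls = np.array([variable_labels(t, var) for t in labels])
        bins = np.arange(n_bins) if info_bins is None else np.asarray(info_bins)
        x[np.ix_(np.arange(n_cells), np.nonzero(cls == 1)[0], bins)] += sep
    return x, labels


class TestDecodeAcrossDays:
    def test_separable_classes_decode_near_one(self):
        rng = np.random.default_rng(0)
        x, labels = _make_data(rng, 8, 10, 20, sep=4.0)
        curve = decode_across_days(x, labels, None, None, "context",
                                   n_iter=20, seed=0)
        assert curve.mean_performance.mean() > 0.95

    def test_label_independent_activity_decodes_at_chance(self):
        rng = np.random.default_rng(1)
        x, labels = _make_data(rng, 10, 10, 15, sep=0.0)
        curve = decode_across_days(x, labels, None, None, "context",
                                   n_iter=30, seed=0)
        assert abs(curve.mean_performance.mean() - 0.5) < 0.05

    def test_information_confined_to_tuned_bins(self):
        rng = np.random.default_rng(2)
        info = np.arange(10, 15)
        x, labels = _make_data(rng, 10, 8, 30, sep=4.0, info_bins=info)
        curve = decode_across_days(x, labels, None, None, "context",
                                   n_iter=25, seed=0)
        assert curve.mean_performance[info].mean() > 0.9
        quiet = np.setdiff1d(np.arange(30), info)
        assert abs(curve.mean_performance[quiet].mean() - 0.5) < 0.06

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        x, labels = _make_data(rng, 6, 5, 10, sep=1.0)
        c1 = decode_across_days(x, labels, None, None, "motor", n_iter=10, seed=9)
        c2 = decode_across_days(x, labels, None, None, "motor", n_iter=10, seed=9)
        np.testing.assert_array_equal(c1.mean_performance, c2.mean_performance)

    def test_cross_day_uses_test_day_tensor(self):
        rng = np.random.default_rng(4)
        x1, labels = _make_data(rng, 8, 6, 10, sep=3.0)
        # day-2 data with the *same* code: cross-day performance stays high
        x2, labels2 = _make_data(rng, 8, 6, 10, sep=3.0)
        c = decode_across_days(x1, labels, x2, labels2, "context",
                               test_day=2, n_iter=15, seed=0)
        assert c.mean_performance.mean() > 0.9
        # day-2 data with no information: performance falls to chance
        x0, labels0 = _make_data(rng, 8, 6, 10, sep=0.0)
        c0 = decode_across_days(x1, labels, x0, labels0, "context",
                                test_day=2, n_iter=15, seed=0)
        assert abs(c0.mean_performance.mean() - 0.5) < 0.07


def _curve(ci_low, bins=None):
    n = len(ci_low)
    bins = np.arange(n) if bins is None else bins
    return DecodingCurve(variable="post_decision_outcome", unit="single_cell",
                         train_day=1, test_day=1, bin_indices=np.asarray(bins),
                         bin_times=np.asarray(bins) * 0.1,
                         mean_performance=np.asarray(ci_low) + 0.1,
                         ci_low=np.asarray(ci_low),
                         ci_high=np.asarray(ci_low) + 0.2, n_iter=10)


class TestSignificantEncoding:
    def test_uniformly_high_ci_is_significant(self):
        calls = significant_encoding(_curve([0.6] * 90), trial_end_bin=60)
        assert any(c.significant for c in calls)

    def test_four_bin_run_not_significant(self):
        ci = np.full(90, 0.4)
        ci[10:14] = 0.7
        calls = significant_encoding(_curve(ci), trial_end_bin=60)
        assert not any(c.significant for c in calls)

    def test_outcome_region_assignment(self):
        ci = np.full(90, 0.4)
        ci[65:76] = 0.7
        calls = significant_encoding(_curve(ci), trial_end_bin=60)
        assert [c.assigned_variable for c in calls if c.significant] == \
            ["post_trial_outcome"]
        ci2 = np.full(90, 0.4)
        ci2[30:40] = 0.7
        calls2 = significant_encoding(_curve(ci2), trial_end_bin=60)
        assert [c.assigned_variable for c in calls2 if c.significant] == \
            ["post_decision_outcome"]

    def test_non_outcome_variable_assigned_to_itself(self):
        curve = _curve([0.6] * 20)
        curve.variable = "context"
        calls = significant_encoding(curve, trial_end_bin=60)
        assert calls[0].assigned_variable == "context"


class TestPseudopopulation:
    def _experiments(self, rng, sep, n_exp=2, n_cells=6):
        out = []
        for _ in range(n_exp):
            x, labels = _make_data(rng, 8, n_cells, 12, sep=sep)
            out.append({1: (x, labels)})
        return out

    def test_informative_pool_decodes_above_chance(self):
        rng = np.random.default_rng(5)
        exps = self._experiments(rng, sep=2.0)
        c = pseudopopulation_decode(exps, "context", n_iter=10, seed=0)
        assert c.mean_performance.mean() > 0.9

    def test_null_pool_decodes_at_chance(self):
        rng = np.random.default_rng(6)
        exps = self._experiments(rng, sep=0.0)
        c = pseudopopulation_decode(exps, "context", n_iter=15, seed=0)
        assert abs(c.mean_performance.mean() - 0.5) < 0.06

    def test_more_cells_do_not_decode_worse(self):
        rng = np.random.default_rng(7)
        perfs = []
        for n_cells in (2, 10, 30):
            exps = self._experiments(rng, sep=0.35, n_cells=n_cells)
            c = pseudopopulation_decode(exps, "context", n_iter=15, seed=1)
            perfs.append(c.mean_performance.mean())
        assert perfs[2] > perfs[0] - 0.03  # non-decreasing up to noise

    def test_single_experiment_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            pseudopopulation_decode(self._experiments(rng, 0.0, n_exp=1),
                                    "context")


class TestSubsampleControls:
    def test_equal_n_full_size_is_identity(self):
        rng = np.random.default_rng(9)
        x, labels = _make_data(rng, 6, 8, 46, sep=1.0)
        res = subsample_controls(x, labels, "context", "equal_n", 8, seed=0)
        np.testing.assert_array_equal(res.cells, np.arange(8))

    def test_match_performance_reaches_target(self):
        rng = np.random.default_rng(10)
        x, labels = _make_data(rng, 8, 30, 46, sep=2.0)
        res = subsample_controls(x, labels, "context", "match_performance",
                                 0.9, seed=0, n_iter=10)
        assert res.reached
        assert res.achieved >= 0.9 - 0.02

    def test_stronger_tuning_needs_fewer_cells(self):
        rng = np.random.default_rng(11)
        sizes = []
        for sep in (0.8, 3.0):
            x, labels = _make_data(rng, 8, 30, 46, sep=sep)
            res = subsample_controls(x, labels, "context", "match_performance",
                                     0.9, seed=1, n_iter=10)
            assert res.reached
            sizes.append(len(res.cells))
        assert sizes[1] <= sizes[0]

    def test_unreachable_target_flagged(self):
        rng = np.random.default_rng(12)
        x, labels = _make_data(rng, 6, 5, 46, sep=0.0)
        res = subsample_controls(x, labels, "context", "match_performance",
                                 0.95, seed=0, n_iter=5)
        assert not res.reached and res.cells is None
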