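"""Trial-balanced single-cell and population response analyses.

Because trained animals make more correct than incorrect responses,
every comparison across trial groups first balances trial counts by
resampling (without replacement for balancing, with replacement for
bootstrap-style preference calls). Stability of single-cell responses is
measured as the Pearson correlation between odd-trial means on day 1 and
even-trial means on later days; population structure is compared with
cross-validated population-vector correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._stats import find_runs, pearson_rows, signed_rank_p
from .task import CLASS_RULES

__all__ = [
    "PreferenceResult",
    "PvCorrelationResult",
    "balance_trials",
    "preference_test",
    "crossday_response_cc",
    "population_vector_correlation",
    "latency_sort",
]


def balance_trials(labels: Sequence, seed: int = 0, n_iter: int = 100,
                   groups: Optional[Sequence] = None) -> List[Dict[object, np.ndarray]]:
    """Resample trials without replacement to the smallest group size.

    ``labels`` assigns each trial to a group; each of the ``n_iter``
    iterations draws min-group-size indices per group, without
    replacement within the iteration. ``groups`` optionally names the
    expected groups; one with no trials raises, naming the group.
    """
    labels = np.asarray(labels)
    keys = np.unique(labels) if groups is None else list(groups)
    group_idx = {}
    for g in keys:
        idx = np.nonzero(labels == g)[0]
        if idx.size == 0:
            raise ValueError(f"group {g!r} has 0 trials")
        group_idx[g] = idx
    groups = group_idx
    m = min(idx.size for idx in groups.values())
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        out.append({g: rng.choice(idx, size=m, replace=False)
                    for g, idx in groups.items()})
    return out


@dataclass
class PreferenceResult:
    cell_id: int
    grouping: str
    preferred_class: Optional[int]
    significant: bool
    run_start_bin: Optional[int]
    run_length: Optional[int]
    p_by_bin: np.ndarray


def preference_test(
    cell_tensor: np.ndarray,
    labels: Sequence,
    grouping: str,
    n_iter: int = 100,
    alpha: float = 0.05,
    min_run: int = 5,
    seed: int = 0,
    cell_id: int = 0,
) -> PreferenceResult:
    """Bin-wise preference call for one cell.

    ``cell_tensor`` is trials x bins; ``labels`` the trial types. Trials
    are grouped into the two classes of ``grouping`` (a key of
    ``CLASS_RULES``), resampled with replacement (``n_iter`` iterations)
    to the smaller class size, and compared bin-by-bin with a two-sided
    Wilcoxon signed-rank test pairing resampled trials within each
    iteration; iterations are combined by the median p-value per bin
    (which tracks the typical resample and keeps the bin-level test
    calibrated, unlike cross-iteration pairing of the means). The
    cell is significant iff >= ``min_run`` consecutive bins have combined
    p < ``alpha``; the preferred class is the one with higher mean
    activity in the first qualifying run.
    """
    x = np.asarray(cell_tensor, dtype=float)
    labels = np.asarray(labels)
    rule = CLASS_RULES[grouping]
    cls = np.array([rule.get(str(l), -1) for l in labels])
    idx0 = np.nonzero(cls == 0)[0]
    idx1 = np.nonzero(cls == 1)[0]
    if idx0.size < 2 or idx1.size < 2:
        raise ValueError(f"both classes need >= 2 trials for {grouping!r}")
    m = min(idx0.size, idx1.size)
    rng = np.random.default_rng(seed)

    take0 = rng.choice(idx0, size=(n_iter, m), replace=True)
    take1 = rng.choice(idx1, size=(n_iter, m), replace=True)
    d = x[take0] - x[take1]                    # (iter, m, bins)
    if np.all(d == 0):
        return PreferenceResult(cell_id, grouping, None, False, None, None,
                                np.ones(x.shape[1]))
    p_iter = signed_rank_p(d, axis=1)          # (iter, bins)
    p_bin = np.median(p_iter, axis=0)
    runs = find_runs(p_bin < alpha, min_run)
    if not runs:
        return PreferenceResult(cell_id, grouping, None, False, None, None, p_bin)
    start, length = runs[0]
    sl = slice(start, start + length)
    mean0 = x[idx0][:, sl].mean()
    mean1 = x[idx1][:, sl].mean()
    preferred = 0 if mean0 >= mean1 else 1
    return PreferenceResult(cell_id, grouping, preferred, True, start, length, p_bin)


def crossday_response_cc(
    tensor_day1: np.ndarray,
    labels_day1: Sequence,
    tensor_dayk: np.ndarray,
    labels_dayk: Sequence,
    classes: Sequence[Sequence[str]],
) -> np.ndarray:
    """Per-cell response correlation between day 1 and day k.

    For each class (a set of trial types, e.g. one trial type or one
    preferred-variable group), the day-1 odd-trial mean timecourse and the
    day-k even-trial mean timecourse are computed; the per-cell Pearson
    correlation is taken over the concatenation across classes. Cells
    with a zero-variance mean response yield NaN (excluded upstream).
    """
    t1 = np.asarray(tensor_day1, dtype=float)
    tk = np.asarray(tensor_dayk, dtype=float)
    l1 = np.asarray(labels_day1)
    lk = np.asarray(labels_dayk)
    segs1, segsk = [], []
    for cls in classes:
        cls = set(cls)
        i1 = np.nonzero(np.isin(l1, list(cls)))[0]
        ik = np.nonzero(np.isin(lk, list(cls)))[0]
        if i1.size < 1 or ik.size < 1:
            raise ValueError(f"class {sorted(cls)} has no trials on one day")
        segs1.append(t1[:, i1[0::2], :].mean(axis=1))
        segsk.append(tk[:, ik[1::2], :].mean(axis=1))
    a = np.concatenate(segs1, axis=1)
    b = np.concatenate(segsk, axis=1)
    return pearson_rows(a, b)


@dataclass
class PvCorrelationResult:
    """Mean bins x bins PV-correlation matrices per test day."""

    matrices: Dict[int, np.ndarray]
    diag_iters: Dict[int, np.ndarray]  # (n_iter, bins) diagonal values
    n_cells_resampled: int
    condition: Tuple[str, ...]


def _pv_corr_matrix(pv_a: np.ndarray, pv_b: np.ndarray) -> np.ndarray:
    """corr over cells between every bin pair; pv_* are (cells, bins)."""
    a = pv_a - pv_a.mean(axis=0, keepdims=True)
    b = pv_b - pv_b.mean(axis=0, keepdims=True)
    a /= np.maximum(np.linalg.norm(a, axis=0, keepdims=True), 1e-12)
    b /= np.maximum(np.linalg.norm(b, axis=0, keepdims=True), 1e-12)
    return a.T @ b


def population_vector_correlation(
    tensors_by_day: Dict[int, Tuple[np.ndarray, Sequence]],
    condition: Sequence[str],
    n_cells: int,
    n_iter: int = 100,
    seed: int = 0,
) -> PvCorrelationResult:
    """Cross-validated PV correlation matrices, day 1 vs each day.

    ``tensors_by_day`` maps day -> (cells x trials x bins tensor, labels).
    Per iteration the population is resampled (without replacement) to
    ``n_cells`` cells and trials are resampled within ``condition`` (a set
    of trial types) balanced to the smallest per-type count. Within day 1
    the two population vectors come from non-overlapping trial halves;
    for days k > 1 all resampled day-1 trials are compared to all
    resampled day-k trials. Matrices are averaged over iterations.
    """
    days = sorted(tensors_by_day)
    ref = days[0]
    t_ref, l_ref = tensors_by_day[ref]
    total_cells = t_ref.shape[0]
    if total_cells < n_cells:
        raise ValueError(f"only {total_cells} cells available, need {n_cells}")
    rng = np.random.default_rng(seed)
    condition = tuple(condition)

    def _cond_idx(labels):
        labels = np.asarray(labels)
        by_type = {tt: np.nonzero(labels == tt)[0] for tt in condition}
        for tt, idx in by_type.items():
            if idx.size == 0:
                raise ValueError(f"trial type {tt!r} absent")
        return by_type

    idx_by_day = {d: _cond_idx(tensors_by_day[d][1]) for d in days}
    n_bins = t_ref.shape[2]
    mats = {d: np.zeros((n_bins, n_bins)) for d in days}
    diags = {d: np.empty((n_iter, n_bins)) for d in days}

    for it in range(n_iter):
        cells = rng.choice(total_cells, size=n_cells, replace=False)
        # day 1: disjoint halves, balanced per type
        half1_idx, half2_idx = [], []
        for tt, idx in idx_by_day[ref].items():
            perm = rng.permutation(idx)
            h = idx.size // 2
            if h == 0:
                raise ValueError(f"trial type {tt!r} has < 2 trials on day {ref}")
            half1_idx.append(perm[:h])
            half2_idx.append(perm[h:2 * h])
        half1 = np.concatenate(half1_idx)
        half2 = np.concatenate(half2_idx)
        pv_ref_1 = t_ref[np.ix_(cells, half1)].mean(axis=1)
        pv_ref_2 = t_ref[np.ix_(cells, half2)].mean(axis=1)
        m = _pv_corr_matrix(pv_ref_1, pv_ref_2)
        mats[ref] += m
        diags[ref][it] = np.diag(m)
        # all balanced-resampled day-1 trials for the cross-day comparisons
        m_min = {tt: idx.size for tt, idx in idx_by_day[ref].items()}
        for d in days[1:]:
            t_d, _ = tensors_by_day[d]
            sel_ref, sel_d = [], []
            for tt in condition:
                k = min(idx_by_day[ref][tt].size, idx_by_day[d][tt].size)
                sel_ref.append(rng.choice(idx_by_day[ref][tt], size=k, replace=False))
                sel_d.append(rng.choice(idx_by_day[d][tt], size=k, replace=False))
            pv_a = t_ref[np.ix_(cells, np.concatenate(sel_ref))].mean(axis=1)
            pv_b = t_d[np.ix_(cells, np.concatenate(sel_d))].mean(axis=1)
            m = _pv_corr_matrix(pv_a, pv_b)
            mats[d] += m
            diags[d][it] = np.diag(m)
        del m_min

    for d in days:
        mats[d] /= n_iter
    return PvCorrelationResult(matrices=mats, diag_iters=diags,
                               n_cells_resampled=n_cells, condition=condition)


def diagonal_exceeds(correct: PvCorrelationResult,
                     incorrect: PvCorrelationResult, day: int) -> np.ndarray:
    """Per-bin flag: mean correct-trial diagonal > incorrect 95th percentile."""
    mean_correct = correct.diag_iters[day].mean(axis=0)
    thresh = np.percentile(incorrect.diag_iters[day], 95, axis=0)
    return mean_correct > thresh


def latency_sort(tensor: np.ndarray) -> np.ndarray:
    """Cell ordering by arg-max bin of the odd-trial mean response.

    ``tensor`` is cells x trials x bins; sorting uses trials 0, 2, 4, ...
    (the cross-validation "sorting" half). Ties break by cell id. The
    returned permutation is applied by the caller to even-trial means.
    """
    t = np.asarray(tensor, dtype=float)
    if t.size == 0:
        raise ValueError("empty tensor")
    odd_mean = t[:, 0::2, :].mean(axis=1)
    peak = odd_mean.argmax(axis=1)
    ids = np.arange(t.shape[0])
    return np.lexsort((ids, peak))
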