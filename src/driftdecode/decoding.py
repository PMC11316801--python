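"""Per-timebin linear-SVM decoding of task variables across days.

Classifiers are trained on reference-day activity and tested within or
across days, at three unit levels: single cell (1 feature), one
experiment's population, and pseudo-populations pooled across
experiments. Trials are homogenized per iteration (equal per-type counts
resampled with replacement from *disjoint* underlying halves, so train
and test never share a trial), and per-bin performance is summarized by
the mean and 5th/95th bootstrap percentiles over iterations. A variable
is significantly encoded when the lower 5th CI stays above chance (0.5)
for at least 5 consecutive bins; outcome calls are split into
post-decision vs post-trial by the position of the qualifying run
relative to the trial-end bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from ._stats import find_runs
from .task import CLASS_RULES, STABILITY_WINDOWS, TRIAL_TYPES, VARIABLE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "TaskVariableSpec",
    "VARIABLES",
    "DecodingCurve",
    "EncodingCall",
    "variable_labels",
    "homogenize_and_split",
    "decode_across_days",
    "significant_encoding",
    "pseudopopulation_decode",
    "subsample_controls",
]


@dataclass(frozen=True)
class TaskVariableSpec:
    """A decodable binary task variable and its stability window."""

    name: str
    label_rule: Dict[str, int]
    window: Tuple[float, float]       # seconds, 1.5 s wide
    region: str                       # "pre_trial_end" | "post_trial_end"


VARIABLES: Dict[str, TaskVariableSpec] = {
    name: TaskVariableSpec(
        name=name,
        label_rule=dict(CLASS_RULES[name]),
        window=STABILITY_WINDOWS[name],
        region="post_trial_end" if name == "post_trial_outcome" else "pre_trial_end",
    )
    for name in VARIABLE_NAMES
}


def variable_labels(trial_type: str, variable: str) -> int:
    """Binary class of a trial type under a variable's partition."""
    if trial_type == "aborted":
        raise ValueError("aborted trials have no task-variable label")
    return CLASS_RULES[variable][trial_type]


def homogenize_and_split(
    labels: Sequence,
    rng: np.random.Generator,
    target: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Equal-per-type train/test trial sets from disjoint halves.

    The original trials of each type are partitioned into two disjoint
    halves; each half is resampled with replacement to ``target`` (default
    the session's minimum per-type count), so the two returned index sets
    share no underlying trial and hold equal counts of all four types.
    """
    labels = np.asarray(labels)
    by_type = {}
    for tt in TRIAL_TYPES:
        idx = np.nonzero(labels == tt)[0]
        if idx.size < 2:
            raise ValueError(f"trial type {tt!r} has {idx.size} trials; need >= 2")
        by_type[tt] = idx
    if target is None:
        target = min(idx.size for idx in by_type.values())
    train, test = [], []
    for tt, idx in by_type.items():
        perm = rng.permutation(idx)
        h = idx.size // 2
        train.append(rng.choice(perm[:h], size=target, replace=True))
        test.append(rng.choice(perm[h:], size=target, replace=True))
    return np.concatenate(train), np.concatenate(test)


@dataclass
class DecodingCurve:
    """Per-timebin classifier performance with bootstrap CIs."""

    variable: str
    unit: str                 # single_cell | experiment_population | pseudopopulation
    train_day: int
    test_day: int
    bin_indices: np.ndarray   # bins the curve covers (indices into the tensor)
    bin_times: np.ndarray     # seconds from trial start
    mean_performance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_iter: int
    per_iteration: Optional[np.ndarray] = None  # (n_iter, bins)


def _fit_score_bins(
    x_train: np.ndarray, y_train: np.ndarray,
    x_test: np.ndarray, y_test: np.ndarray,
    bins: np.ndarray, C: float,
) -> np.ndarray:
    """Accuracy per bin; x_* are (cells, trials, bins)."""
    out = np.empty(bins.size)
    for j, b in enumerate(bins):
        xt = x_train[:, :, b].T
        if np.unique(y_train).size < 2:
            out[j] = np.nan
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(xt, y_train)
        out[j] = clf.score(x_test[:, :, b].T, y_test)
    return out


def decode_across_days(
    tensor_train: np.ndarray,
    labels_train: Sequence,
    tensor_test: Optional[np.ndarray],
    labels_test: Optional[Sequence],
    variable: str,
    train_day: int = 1,
    test_day: int = 1,
    unit: str = "experiment_population",
    n_iter: int = 100,
    seed: int = 0,
    bins: Optional[np.ndarray] = None,
    C: float = 1.0,
    bin_duration_s: float = 0.1,
    keep_iterations: bool = False,
) -> DecodingCurve:
    """Train per-bin linear SVMs on the reference day, test within/across days.

    ``tensor_*`` are cells x trials x bins (single-cell unit: one cell).
    Same-day testing uses the held-out homogenized half; cross-day testing
    uses homogenized trials of the test day (``tensor_test``/``labels_test``;
    pass ``None`` for within-day). ``bins`` restricts the curve to a subset
    of timebins (e.g. a stability window); default is every bin.
    """
    x_tr = np.asarray(tensor_train, dtype=float)
    if x_tr.ndim == 2:  # single cell given as trials x bins
        x_tr = x_tr[None, :, :]
    same_day = tensor_test is None
    if same_day:
        x_te, labels_te = x_tr, np.asarray(labels_train)
        test_day = train_day
    else:
        x_te = np.asarray(tensor_test, dtype=float)
        if x_te.ndim == 2:
            x_te = x_te[None, :, :]
        labels_te = np.asarray(labels_test)
    labels_tr = np.asarray(labels_train)
    rule = CLASS_RULES[variable]
    if bins is None:
        bins = np.arange(x_tr.shape[2])
    bins = np.asarray(bins, dtype=int)

    rng = np.random.default_rng(seed)
    perf = np.full((n_iter, bins.size), np.nan)
    for it in range(n_iter):
        tr_idx, heldout_idx = homogenize_and_split(labels_tr, rng)
        if same_day:
            te_idx = heldout_idx
        else:
            _, te_idx = homogenize_and_split(labels_te, rng)
        y_tr = np.array([rule[t] for t in labels_tr[tr_idx]])
        y_te = np.array([rule[t] for t in labels_te[te_idx]])
        perf[it] = _fit_score_bins(x_tr[:, tr_idx, :], y_tr,
                                   x_te[:, te_idx, :], y_te, bins, C)
    n_bad = int(np.isnan(perf).any(axis=1).sum())
    if n_bad:
        logger.info("decode_across_days: %d/%d iterations had degenerate bins",
                    n_bad, n_iter)
    return DecodingCurve(
        variable=variable, unit=unit, train_day=train_day, test_day=test_day,
        bin_indices=bins, bin_times=bins * bin_duration_s,
        mean_performance=np.nanmean(perf, axis=0),
        ci_low=np.nanpercentile(perf, 5, axis=0),
        ci_high=np.nanpercentile(perf, 95, axis=0),
        n_iter=n_iter,
        per_iteration=perf if keep_iterations else None,
    )


@dataclass
class EncodingCall:
    significant: bool
    qualifying_run: Optional[Tuple[int, int]]
    assigned_variable: Optional[str]


def significant_encoding(curve: DecodingCurve, trial_end_bin: int = 60,
                         min_run: int = 5) -> List[EncodingCall]:
    """Significant-encoding calls from a curve's lower bootstrap CI.

    Significant iff ci_low > 0.5 for >= ``min_run`` consecutive bins.
    For the outcome partition, runs lying at bins <= ``trial_end_bin``
    are assigned to post_decision_outcome and runs after it to
    post_trial_outcome (a cell may receive both); other variables are
    assigned as themselves. Returns a list of calls (empty run -> one
    non-significant call).
    """
    above = curve.ci_low > 0.5
    idx = curve.bin_indices
    calls: List[EncodingCall] = []
    is_outcome = curve.variable in ("post_decision_outcome", "post_trial_outcome",
                                    "outcome")
    if is_outcome:
        pre = above & (idx <= trial_end_bin)
        post = above & (idx > trial_end_bin)
        for mask, name in ((pre, "post_decision_outcome"),
                           (post, "post_trial_outcome")):
            for start, length in find_runs(mask, min_run):
                calls.append(EncodingCall(True, (int(idx[start]), length), name))
    else:
        for start, length in find_runs(above, min_run):
            calls.append(EncodingCall(True, (int(idx[start]), length),
                                      curve.variable))
    if not calls:
        calls.append(EncodingCall(False, None, None))
    return calls


def pseudopopulation_decode(
    experiments: Sequence[Dict[int, Tuple[np.ndarray, Sequence]]],
    variable: str,
    train_day: int = 1,
    test_day: int = 1,
    n_iter: int = 100,
    seed: int = 0,
    bins: Optional[np.ndarray] = None,
    C: float = 1.0,
    bin_duration_s: float = 0.1,
    keep_iterations: bool = False,
) -> DecodingCurve:
    """Decode from pseudo-populations pooled across experiments.

    Each element of ``experiments`` maps day -> (cells x trials x bins,
    labels). Pseudo-trials of a given type are assembled by sampling,
    independently per cell, one of that cell's (train-half or test-day)
    trials of that type; per-type pseudo-trial counts equal the pooled
    minimum per-type count. Cells with an empty class would be dropped;
    session inclusion (>= 2 per type) prevents that upstream.
    """
    if len(experiments) < 2:
        raise ValueError("pseudo-population decoding needs >= 2 experiments")
    rng = np.random.default_rng(seed)
    same_day = test_day == train_day

    tr_data = [(np.asarray(e[train_day][0], float), np.asarray(e[train_day][1]))
               for e in experiments]
    te_data = tr_data if same_day else \
        [(np.asarray(e[test_day][0], float), np.asarray(e[test_day][1]))
         for e in experiments]
    n_bins_total = tr_data[0][0].shape[2]
    if bins is None:
        bins = np.arange(n_bins_total)
    bins = np.asarray(bins, dtype=int)
    rule = CLASS_RULES[variable]

    # pooled per-type pseudo-trial count: min over experiments and types of
    # the *half* counts (halving preserves train/test disjointness)
    def _half_min(data):
        m = []
        for _, labels in data:
            for tt in TRIAL_TYPES:
                c = int((labels == tt).sum())
                if c < 2:
                    raise ValueError(f"trial type {tt!r} has {c} trials")
                m.append(c // 2)
        return min(m)

    target = max(_half_min(tr_data), 2)

    def _gather(data, halves, n_pseudo):
        """Build (total_cells, n_pseudo * 4, bins) pseudo tensor + labels."""
        cols, labs = [], []
        for tt in TRIAL_TYPES:
            per_exp = []
            for (tens, labels), half in zip(data, halves):
                pool = half[tt]
                n_cells = tens.shape[0]
                pick = rng.choice(pool, size=(n_cells, n_pseudo), replace=True)
                per_exp.append(tens[np.arange(n_cells)[:, None], pick, :][:, :, bins])
            cols.append(np.concatenate(per_exp, axis=0))
            labs.extend([rule[tt]] * n_pseudo)
        return np.concatenate(cols, axis=1), np.array(labs)

    perf = np.full((n_iter, bins.size), np.nan)
    for it in range(n_iter):
        tr_halves, te_halves = [], []
        for _, labels in tr_data:
            tr_h, te_h = {}, {}
            for tt in TRIAL_TYPES:
                idx = np.nonzero(labels == tt)[0]
                perm = rng.permutation(idx)
                h = idx.size // 2
                tr_h[tt], te_h[tt] = perm[:h], perm[h:]
            tr_halves.append(tr_h)
            te_halves.append(te_h)
        if not same_day:
            te_halves = []
            for _, labels in te_data:
                te_halves.append({tt: np.nonzero(labels == tt)[0]
                                  for tt in TRIAL_TYPES})
        x_tr, y_tr = _gather(tr_data, tr_halves, target)
        x_te, y_te = _gather(te_data, te_halves, target)
        perf[it] = _fit_score_bins(x_tr, y_tr, x_te, y_te,
                                   np.arange(bins.size), C)
    return DecodingCurve(
        variable=variable, unit="pseudopopulation",
        train_day=train_day, test_day=test_day,
        bin_indices=bins, bin_times=bins * bin_duration_s,
        mean_performance=np.nanmean(perf, axis=0),
        ci_low=np.nanpercentile(perf, 5, axis=0),
        ci_high=np.nanpercentile(perf, 95, axis=0),
        n_iter=n_iter,
        per_iteration=perf if keep_iterations else None,
    )


@dataclass
class SubsampleResult:
    cells: Optional[np.ndarray]
    achieved: Optional[float]
    reached: bool


def _window_performance(tensor, labels, variable, cells, n_iter, seed, C,
                        frame_rate_hz=10.0) -> float:
    t0, t1 = VARIABLES[variable].window
    bins = np.arange(int(round(t0 * frame_rate_hz)),
                     int(round(t1 * frame_rate_hz)) + 1)
    curve = decode_across_days(tensor[cells], labels, None, None, variable,
                               n_iter=n_iter, seed=seed, bins=bins, C=C)
    return float(curve.mean_performance.mean())


def subsample_controls(
    tensor: np.ndarray,
    labels: Sequence,
    variable: str,
    mode: str,
    target,
    seed: int = 0,
    n_iter: int = 20,
    C: float = 1.0,
) -> SubsampleResult:
    """Neuron-count controls for day-1 decoding.

    ``mode="equal_n"``: random subset of fixed size ``target`` (int).
    ``mode="match_performance"``: smallest random subset whose day-1
    window performance reaches ``target`` (fraction, e.g. 0.9), located by
    doubling then bisection over subset size. Unreachable targets return
    a flagged result with no subset.
    """
    tensor = np.asarray(tensor, dtype=float)
    labels = np.asarray(labels)
    n_cells = tensor.shape[0]
    rng = np.random.default_rng(seed)
    if mode == "equal_n":
        k = int(target)
        if k > n_cells:
            raise ValueError(f"requested {k} cells of {n_cells}")
        cells = np.sort(rng.choice(n_cells, size=k, replace=False))
        return SubsampleResult(cells=cells, achieved=None, reached=True)
    if mode != "match_performance":
        raise ValueError(f"unknown mode {mode!r}")

    order = rng.permutation(n_cells)  # nested random subsets

    def perf_at(k: int) -> float:
        return _window_performance(tensor, labels, variable, order[:k],
                                   n_iter, seed, C)

    if perf_at(n_cells) < target:
        return SubsampleResult(cells=None, achieved=perf_at(n_cells), reached=False)
    k = 1
    while k < n_cells and perf_at(k) < target:
        k *= 2
    k = min(k, n_cells)
    lo, hi = max(k // 2, 1), k
    while lo < hi:
        mid = (lo + hi) // 2
        if perf_at(mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    cells = np.sort(order[:hi])
    return SubsampleResult(cells=cells, achieved=perf_at(hi), reached=True)
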