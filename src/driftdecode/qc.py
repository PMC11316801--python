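"""Inclusion gates: session behavior, activity reliability, ROI stability.

Three gates select analyzable sessions and cells:

* **Session inclusion** — behavioral performance above chance (> 0.5) and
  at least 2 trials of each of the four types.
* **Activity reliability** — the Pearson correlation between odd- and
  even-trial mean responses (correct trials) must exceed the 95th
  percentile of the same statistic computed after circularly permuting
  each trial's timecourse at an independent random point (100 iterations).
* **ROI morphological stability** — the structural similarity index (SSI)
  between the 30x30 um windows around an ROI on day 1 and day k must
  exceed the 95th percentile of a null distribution of SSIs against
  random windows of the comparison day's field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from ._stats import pearson_rows
from .task import TRIAL_TYPES, TrialRecord

__all__ = [
    "SessionInclusion",
    "ReliabilityResult",
    "RoiStabilityResult",
    "CellSelection",
    "check_session_inclusion",
    "reliability_test",
    "compute_ssi",
    "roi_stability_test",
    "sample_null_windows",
    "select_cells",
]


@dataclass(frozen=True)
class SessionInclusion:
    n_CL: int
    n_IR: int
    n_IL: int
    n_CR: int
    performance: float
    min_count: int
    included: bool


def check_session_inclusion(trials: Sequence) -> SessionInclusion:
    """Behavioral gate: > 0.5 performance and >= 2 trials of each type.

    Accepts a sequence of :class:`TrialRecord` or of trial-type strings;
    aborted trials are ignored.
    """
    if trials and isinstance(trials[0], TrialRecord):
        labels = [t.trial_type for t in trials if not t.aborted]
    else:
        labels = [t for t in trials if t != "aborted"]
    if not labels:
        raise ValueError("no non-aborted trials in session")
    counts = {tt: labels.count(tt) for tt in TRIAL_TYPES}
    total = sum(counts.values())
    performance = (counts["CL"] + counts["CR"]) / total
    min_count = min(counts.values())
    return SessionInclusion(
        n_CL=counts["CL"], n_IR=counts["IR"], n_IL=counts["IL"], n_CR=counts["CR"],
        performance=performance, min_count=min_count,
        included=(min_count >= 2 and performance > 0.5),
    )


@dataclass
class ReliabilityResult:
    cc_true: float
    null_ccs: np.ndarray
    threshold: float
    reliable: bool
    degenerate: bool = False


def _odd_even_cc(x: np.ndarray) -> float:
    """Correlation of odd- vs even-trial mean timecourses (0-based split)."""
    m_odd = x[0::2].mean(axis=0)
    m_even = x[1::2].mean(axis=0)
    return float(pearson_rows(m_odd[None, :], m_even[None, :])[0])


def reliability_test(correct_trial_matrix: np.ndarray, n_iter: int = 100,
                     seed: int = 0) -> ReliabilityResult:
    """Circular-shuffle reliability criterion for one cell.

    ``correct_trial_matrix`` is trials x bins (correct trials only).
    Each null iteration circularly shifts every trial's bin series by an
    independent uniform offset in [1, bins-1] before recomputing the
    odd/even-mean correlation; reliable iff the true correlation exceeds
    the null's 95th percentile. Zero-variance mean responses make the
    correlation undefined -> not reliable, flagged degenerate.
    """
    x = np.asarray(correct_trial_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise ValueError("need a trials x bins matrix with >= 4 correct trials")
    n_trials, n_bins = x.shape
    rng = np.random.default_rng(seed)

    cc_true = _odd_even_cc(x)
    offsets = rng.integers(1, n_bins, size=(n_iter, n_trials))
    idx = (np.arange(n_bins)[None, None, :] - offsets[:, :, None]) % n_bins
    shuffled = x[np.arange(n_trials)[None, :, None], idx]  # (iter, trial, bin)
    null = pearson_rows(shuffled[:, 0::2].mean(axis=1), shuffled[:, 1::2].mean(axis=1))
    null = np.nan_to_num(null, nan=0.0)
    threshold = float(np.percentile(null, 95))
    degenerate = not np.isfinite(cc_true)
    reliable = (not degenerate) and cc_true > threshold
    return ReliabilityResult(cc_true=cc_true if np.isfinite(cc_true) else np.nan,
                             null_ccs=null, threshold=threshold,
                             reliable=bool(reliable), degenerate=degenerate)


def compute_ssi(patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Structural similarity between two equally shaped 2-D patches.

    Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic range from
    the pooled pair. Identical constant patches have similarity 1.
    """
    a = np.asarray(patch_a, dtype=float)
    b = np.asarray(patch_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("patches must be 2-D and equally shaped")
    pooled = np.concatenate([a.ravel(), b.ravel()])
    data_range = float(pooled.max() - pooled.min())
    if data_range == 0:
        return 1.0
    win = min(11, a.shape[0] - (1 - a.shape[0] % 2), a.shape[1] - (1 - a.shape[1] % 2))
    return float(structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, K1=0.01, K2=0.03,
        use_sample_covariance=False, data_range=data_range, win_size=win))


def _corr2d(a: np.ndarray, b: np.ndarray) -> float:
    r = pearson_rows(a.ravel()[None, :], b.ravel()[None, :])[0]
    return float(r) if np.isfinite(r) else 0.0


@dataclass
class RoiStabilityResult:
    ssi_true: float
    null_ssis: np.ndarray
    threshold: float
    stable: bool
    metric: str


def roi_stability_test(
    patch_day1: np.ndarray,
    patch_dayk: np.ndarray,
    null_windows: np.ndarray,
    metric: str = "ssim",
) -> RoiStabilityResult:
    """ROI stability: true day-1 vs day-k similarity against a window null.

    ``null_windows`` is a stack (>= 50) of windows sampled from the
    comparison day's field away from the true ROI; the threshold is the
    null's 95th percentile. ``metric`` is "ssim" or "corr2d".
    """
    null_windows = np.asarray(null_windows, dtype=float)
    if null_windows.ndim != 3 or null_windows.shape[0] < 50:
        raise ValueError("need >= 50 null windows (stack of 2-D patches)")
    sim = compute_ssi if metric == "ssim" else _corr2d if metric == "corr2d" else None
    if sim is None:
        raise ValueError(f"unknown metric {metric!r}")
    ssi_true = sim(patch_day1, patch_dayk)
    null = np.array([sim(patch_day1, w) for w in null_windows])
    threshold = float(np.percentile(null, 95))
    return RoiStabilityResult(ssi_true=float(ssi_true), null_ssis=null,
                              threshold=threshold,
                              stable=bool(ssi_true > threshold), metric=metric)


def sample_null_windows(field_image: np.ndarray, center: Sequence[int],
                        window_px: int, n_windows: int = 100,
                        seed: int = 0, min_dist: Optional[int] = None) -> np.ndarray:
    """Random windows from a field image, >= one window-width from ``center``."""
    fld = np.asarray(field_image, dtype=float)
    h, w = fld.shape
    p = window_px
    if min_dist is None:
        min_dist = p
    rng = np.random.default_rng(seed)
    cy, cx = center
    out = np.empty((n_windows, p, p))
    got = 0
    attempts = 0
    while got < n_windows:
        attempts += 1
        if attempts > 100 * n_windows:
            raise RuntimeError("could not place enough null windows")
        y = int(rng.integers(0, h - p + 1))
        x = int(rng.integers(0, w - p + 1))
        if abs(y + p // 2 - cy) < min_dist and abs(x + p // 2 - cx) < min_dist:
            continue
        out[got] = fld[y:y + p, x:x + p]
        got += 1
    return out


@dataclass
class CellSelection:
    """Included cell indices per (day 1, day k) pair, plus the strict set."""

    pairwise: Dict[int, np.ndarray] = field(default_factory=dict)
    strict: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def select_cells(
    reliable: np.ndarray,
    stable: np.ndarray,
    session_included: np.ndarray,
) -> CellSelection:
    """Combine the three gates into per-day-pair cell sets.

    ``reliable``: (n_days, n_cells) bool; ``stable``: (n_days, n_cells)
    bool for the (day 1, day k) ROI comparison (row 0, the day-1 self
    comparison, is ignored and treated as True); ``session_included``:
    (n_days,) bool. For the (1, k) pair a cell is included iff reliable on
    both days, ROI-stable for the pair, and both sessions pass the
    behavioral gate. ``strict`` is the 5-day (all-days) intersection.
    """
    reliable = np.asarray(reliable, dtype=bool)
    stable = np.asarray(stable, dtype=bool)
    session_included = np.asarray(session_included, dtype=bool)
    n_days, n_cells = reliable.shape
    sel = CellSelection()
    strict_mask = reliable[0] & session_included[0]
    for k in range(1, n_days):
        ok = (reliable[0] & reliable[k] & stable[k]
              & session_included[0] & session_included[k])
        sel.pairwise[k + 1] = np.nonzero(ok)[0]
        strict_mask &= reliable[k] & stable[k] & session_included[k]
    sel.strict = np.nonzero(strict_mask)[0]
    return sel
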