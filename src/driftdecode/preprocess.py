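"""Neuropil correction, ΔF/F(%) and trial alignment.

The corrected somatic fluorescence for frame *n* is

    F_corrected(n) = F_soma(n) - alpha * (F_neuropil(n) - mean(F_neuropil))

with alpha chosen in [0, 1] per neuron to minimize |Pearson correlation|
between the corrected trace and the neuropil trace. ΔF/F is then

    dFF(%) = 100 * (F_n - F0) / F0

where F0 is the mode of the corrected-fluorescence density distribution
over the whole time series (Gaussian KDE, Silverman bandwidth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gaussian_kde

from .task import TrialRecord

__all__ = [
    "FluorescenceRecord",
    "DffTrace",
    "TrialTensor",
    "estimate_alpha",
    "neuropil_correct",
    "estimate_f0",
    "compute_dff",
    "align_to_trials",
    "preprocess_day",
]

ALPHA_GRID_STEP = 0.001


@dataclass
class FluorescenceRecord:
    """Raw and corrected fluorescence for one neuron (a.u. per frame)."""

    f_soma_trace: np.ndarray
    f_neuropil_trace: np.ndarray
    alpha: float
    neuropil_mean: float
    f_corrected_trace: np.ndarray


@dataclass
class DffTrace:
    f0: float
    dff_trace: np.ndarray  # percent per frame


@dataclass
class TrialTensor:
    """Trial-aligned ΔF/F: cells x trials x timebins (aborted trials dropped).

    ``labels`` holds each kept trial's type (CL/IR/IL/CR); landmark bins at
    defaults are start 0, decision 30, trial end 60 (bin = one 0.1-s frame).
    """

    values: np.ndarray        # (cells, trials, bins)
    labels: np.ndarray        # (trials,) unicode
    bin_duration_s: float
    window: Tuple[float, float]
    day: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_times(self) -> np.ndarray:
        return self.window[0] + self.bin_duration_s * np.arange(self.n_bins)


def _alpha_abs_corr_grid(f_soma: np.ndarray, f_neuropil: np.ndarray,
                         alphas: np.ndarray) -> np.ndarray:
    """|corr(F_soma - a*(N - mean N), N)| on a grid, by moment algebra.

    corr(a) = (cov_sn - a var_n) / sqrt(var_n * (var_s - 2a cov_sn + a^2 var_n));
    an undefined correlation (zero-variance corrected trace) counts as 0.
    """
    s = f_soma - f_soma.mean()
    n = f_neuropil - f_neuropil.mean()
    var_s = float(s @ s)
    var_n = float(n @ n)
    cov_sn = float(s @ n)
    num = cov_sn - alphas * var_n
    var_corr = var_s - 2 * alphas * cov_sn + alphas ** 2 * var_n
    var_corr = np.clip(var_corr, 0.0, None)
    denom = np.sqrt(var_corr * var_n)
    tiny = denom <= 1e-12 * max(var_s, var_n, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(tiny, 0.0, num / np.where(tiny, 1.0, denom))
    return np.abs(corr)


def estimate_alpha(f_soma_trace: np.ndarray, f_neuropil_trace: np.ndarray,
                   grid_step: float = ALPHA_GRID_STEP) -> float:
    """Neuropil weight alpha in [0, 1] minimizing |corr(F_corrected, F_neuropil)|.

    Exhaustive evaluation on a grid of resolution ``grid_step`` (the |corr|
    objective is evaluated exactly from first/second moments, so this *is*
    the grid search). A zero-variance neuropil trace makes the correction a
    no-op; alpha = 0 is returned with a warning.
    """
    f_soma_trace = np.asarray(f_soma_trace, dtype=float)
    f_neuropil_trace = np.asarray(f_neuropil_trace, dtype=float)
    if f_soma_trace.shape != f_neuropil_trace.shape:
        raise ValueError("soma and neuropil traces must have equal length")
    if f_soma_trace.size < 100:
        raise ValueError("need >= 100 frames to estimate alpha")
    if not (np.isfinite(f_soma_trace).all() and np.isfinite(f_neuropil_trace).all()):
        raise ValueError("non-finite values in fluorescence traces")
    if np.ptp(f_neuropil_trace) == 0 or np.var(f_neuropil_trace) == 0:
        warnings.warn("zero-variance neuropil trace; correction is a no-op",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    alphas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    obj = _alpha_abs_corr_grid(f_soma_trace, f_neuropil_trace, alphas)
    return float(alphas[int(np.argmin(obj))])


def neuropil_correct(
    f_soma_trace: np.ndarray,
    f_neuropil_trace: np.ndarray,
    alpha: float,
    neuropil_mean: Optional[float] = None,
) -> np.ndarray:
    """F_soma - alpha * (F_neuropil - mean(F_neuropil)), elementwise."""
    f_soma_trace = np.asarray(f_soma_trace, dtype=float)
    f_neuropil_trace = np.asarray(f_neuropil_trace, dtype=float)
    if f_soma_trace.shape != f_neuropil_trace.shape:
        raise ValueError("soma and neuropil traces must have equal length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if neuropil_mean is None:
        neuropil_mean = float(f_neuropil_trace.mean())
    return f_soma_trace - alpha * (f_neuropil_trace - neuropil_mean)


def make_fluorescence_record(f_soma_trace, f_neuropil_trace,
                             alpha: Optional[float] = None) -> FluorescenceRecord:
    if alpha is None:
        alpha = estimate_alpha(f_soma_trace, f_neuropil_trace)
    mu = float(np.mean(f_neuropil_trace))
    corrected = neuropil_correct(f_soma_trace, f_neuropil_trace, alpha, mu)
    return FluorescenceRecord(np.asarray(f_soma_trace, float),
                              np.asarray(f_neuropil_trace, float),
                              float(alpha), mu, corrected)


def estimate_f0(corrected_trace: np.ndarray, method: str = "kde",
                n_grid: int = 512) -> float:
    """Mode of the corrected-fluorescence density distribution.

    ``method="kde"``: Gaussian KDE with Silverman bandwidth evaluated on
    ``n_grid`` points spanning the data range. ``method="hist"`` is a
    histogram-mode alternative for sensitivity checks.
    """
    x = np.asarray(corrected_trace, dtype=float)
    if x.size < 100:
        raise ValueError("need >= 100 frames to estimate F0")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in corrected trace")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        f0 = lo
    elif method == "kde":
        kde = gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(lo, hi, n_grid)
        f0 = float(grid[int(np.argmax(kde(grid)))])
    elif method == "hist":
        counts, edges = np.histogram(x, bins=min(n_grid, max(10, x.size // 20)))
        k = int(np.argmax(counts))
        f0 = float(0.5 * (edges[k] + edges[k + 1]))
    else:
        raise ValueError(f"unknown F0 method {method!r}")
    if f0 <= 0:
        raise ValueError(f"estimated F0 = {f0} <= 0; ΔF/F undefined")
    return f0


def compute_dff(corrected_trace: np.ndarray, f0: float) -> DffTrace:
    """ΔF/F(%) = 100 * (F - F0) / F0, exact elementwise."""
    if not (np.isfinite(f0) and f0 > 0):
        raise ValueError(f"F0 must be finite and > 0, got {f0}")
    x = np.asarray(corrected_trace, dtype=float)
    return DffTrace(f0=float(f0), dff_trace=100.0 * (x - f0) / f0)


def align_to_trials(
    dff: np.ndarray,
    trials: Sequence[TrialRecord],
    window: Tuple[float, float] = (0.0, 9.0),
    frame_rate_hz: float = 10.0,
    day: int = 1,
) -> TrialTensor:
    """Cut per-cell ΔF/F into a cells x trials x bins tensor.

    Bin *b* of trial *t* is ``dff[:, start_frame(t) + b]`` for the
    half-open ``window`` (seconds from trial start); aborted trials are
    dropped. Raises (naming the trial) if the window leaves the recording.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    n_frames = dff.shape[1]
    t0, t1 = window
    b0 = int(round(t0 * frame_rate_hz))
    n_bins = int(round((t1 - t0) * frame_rate_hz))
    kept = [tr for tr in trials if not tr.aborted]
    slabs = []
    for tr in kept:
        lo = tr.start_frame + b0
        hi = lo + n_bins
        if lo < 0 or hi > n_frames:
            raise ValueError(
                f"window {window} exceeds recording for trial {tr.index} "
                f"(frames [{lo}, {hi}) of {n_frames})")
        slabs.append(dff[:, lo:hi])
    values = (np.stack(slabs, axis=1) if slabs
              else np.empty((dff.shape[0], 0, n_bins)))
    labels = np.array([tr.trial_type for tr in kept], dtype="U8")
    return TrialTensor(values=values, labels=labels,
                       bin_duration_s=1.0 / frame_rate_hz,
                       window=(float(t0), float(t1)), day=day)


def preprocess_day(f_soma: np.ndarray, f_neuropil: np.ndarray,
                   f0_method: str = "kde") -> Tuple[np.ndarray, np.ndarray]:
    """Neuropil-correct and ΔF/F every cell of one session.

    Returns ``(dff, alphas)`` with shapes (cells, frames) and (cells,).
    """
    f_soma = np.atleast_2d(np.asarray(f_soma, dtype=float))
    f_neuropil = np.atleast_2d(np.asarray(f_neuropil, dtype=float))
    if f_soma.shape != f_neuropil.shape:
        raise ValueError("soma and neuropil matrices must have equal shapes")
    n_cells = f_soma.shape[0]
    dff = np.empty_like(f_soma)
    alphas = np.empty(n_cells)
    for i in range(n_cells):
        a = estimate_alpha(f_soma[i], f_neuropil[i])
        corrected = neuropil_correct(f_soma[i], f_neuropil[i], a)
        f0 = estimate_f0(corrected, method=f0_method)
        dff[i] = compute_dff(corrected, f0).dff_trace
        alphas[i] = a
    return dff, alphas
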