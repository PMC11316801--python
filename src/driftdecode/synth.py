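"""Synthetic multi-day experiments with ground-truth drifting tuning.

Forward model
-------------
Each cell may be tuned to a subset of the four task variables. A cell
tuned to variable *v* with preferred class *c* emits, on every trial
whose class under *v* equals *c*, a calcium transient

    amplitude(day) * gain(trial) * kernel_v

where ``kernel_v`` is a boxcar on the variable's canonical trial window
convolved with a single-exponential calcium kernel (GCaMP6s-like decay,
``calcium_tau_s``) and peak-normalized to 1; amplitudes are ΔF/F percent.
For cells that retain their tuning, amplitude decays across days as

    amplitude(day) = amplitude(day 1) * exp((1 - day) / tau_v)

and with probability ``turnover_prob`` per day a cell is re-assigned
(fresh preferred classes and amplitude), emulating the tuning turnover by
which other cells become task-tuned on each day.

Somatic fluorescence combines baseline, transients, additive neuropil
contamination with true weight ``neuropil_alpha_true``, and white noise;
the neuropil channel is a shared slow stochastic field signal. ROI image
patches (30x30 um windows) are rendered from a per-day field image,
either at a fixed blob location (stable cells) or relocated on later
days (unstable cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .task import (
    CLASS_RULES,
    ConfigError,
    KERNEL_SUPPORT,
    TaskConfig,
    TrialRecord,
    VARIABLE_NAMES,
    generate_trial_schedule,
)

__all__ = [
    "GroundTruthTuning",
    "DayData",
    "ExperimentBundle",
    "make_response_kernels",
    "make_drifting_tuning",
    "simulate_day_activity",
    "generate_roi_patches",
    "generate_experiment",
    "trial_classes",
]


def trial_classes(trials: Sequence[TrialRecord], variable: str) -> np.ndarray:
    """Binary class of each non-aborted trial under a variable's partition."""
    rule = CLASS_RULES[variable]
    return np.array([rule[t.trial_type] for t in trials if not t.aborted], dtype=np.int8)


def make_response_kernels(config: TaskConfig) -> Dict[str, np.ndarray]:
    """Effective per-bin response kernels (boxcar * calcium kernel, peak 1).

    Keys are variable names; each kernel spans one trial
    (``trial_len_frames`` bins) and is nonnegative with positive sum.
    """
    n = config.trial_len_frames
    fr = config.frame_rate_hz
    t = np.arange(0, 5 * config.calcium_tau_s, 1.0 / fr)
    calcium = np.exp(-t / config.calcium_tau_s)
    calcium /= calcium.sum()
    kernels = {}
    for v in VARIABLE_NAMES:
        t0, t1 = KERNEL_SUPPORT[v]
        box = np.zeros(n)
        box[int(round(t0 * fr)):int(round(t1 * fr))] = 1.0
        eff = np.convolve(box, calcium)[:n]
        kernels[v] = eff / eff.max()
    return kernels


@dataclass
class GroundTruthTuning:
    """Per-cell, per-day ground truth of the drifting-tuning forward model.

    Arrays are indexed ``[day, cell, variable]`` (days 0-based internally;
    day *d* in the decay law is ``1 + day_index``). ``retained[day, cell]``
    is False once a cell has been re-assigned by turnover, after which its
    amplitude/preference restart rather than follow the day-1 decay.
    """

    variables: Tuple[str, ...]
    tuned: np.ndarray            # (n_days, n_cells, n_vars) bool
    preferred: np.ndarray        # (n_days, n_cells, n_vars) int8 in {0,1}
    amplitude: np.ndarray        # (n_days, n_cells, n_vars) ΔF/F %
    tau: Dict[str, float]        # variable -> days (may be inf)
    kernels: Dict[str, np.ndarray]
    baseline: np.ndarray         # (n_cells,) a.u.
    turnover_prob: float
    retained: np.ndarray         # (n_days, n_cells) bool

    @property
    def n_days(self) -> int:
        return self.tuned.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tuned.shape[1]


def make_drifting_tuning(
    config: TaskConfig,
    tau_by_variable: Dict[str, float],
    seed: int,
    turnover_prob: Optional[float] = None,
) -> GroundTruthTuning:
    """Draw a population's tuning and roll it forward across days.

    Each cell is tuned to each variable independently with probability
    ``config.tuned_fraction``; day-1 amplitudes are exponentially
    distributed with mean ``config.amplitude_mean`` (ΔF/F %).
    """
    for v in VARIABLE_NAMES:
        tau = tau_by_variable.get(v, np.inf)
        if not (tau > 0):
            raise ConfigError(f"tau for {v!r} must be > 0 (or inf), got {tau!r}")
    if turnover_prob is None:
        turnover_prob = config.turnover_prob

    rng = np.random.default_rng(seed)
    n_days, n_cells, n_vars = config.n_days, config.n_cells, len(VARIABLE_NAMES)
    tau_arr = np.array([tau_by_variable.get(v, np.inf) for v in VARIABLE_NAMES])

    def draw_assignment(n: int):
        tuned = rng.random((n, n_vars)) < config.tuned_fraction
        pref = rng.integers(0, 2, size=(n, n_vars)).astype(np.int8)
        # gamma amplitudes: shape controls heterogeneity (shape 1 = exponential)
        amp = rng.gamma(config.amplitude_shape,
                        config.amplitude_mean / config.amplitude_shape,
                        size=(n, n_vars)) * tuned
        return tuned, pref, amp

    tuned = np.zeros((n_days, n_cells, n_vars), dtype=bool)
    pref = np.zeros((n_days, n_cells, n_vars), dtype=np.int8)
    amp = np.zeros((n_days, n_cells, n_vars))
    retained = np.ones((n_days, n_cells), dtype=bool)

    tuned[0], pref[0], amp[0] = draw_assignment(n_cells)
    anchor_day = np.zeros(n_cells, dtype=int)  # day index the decay restarts from
    for d in range(1, n_days):
        flip = rng.random(n_cells) < turnover_prob
        retained[d] = retained[d - 1] & ~flip
        tuned[d] = tuned[d - 1]
        pref[d] = pref[d - 1]
        if flip.any():
            t_new, p_new, a_new = draw_assignment(int(flip.sum()))
            tuned[d, flip] = t_new
            pref[d, flip] = p_new
            amp[d, flip] = a_new            # fresh amplitude at re-assignment
            anchor_day[flip] = d
        keep = ~flip
        # decay relative to each cell's anchor day (day 1 for never-flipped)
        dt = (d - anchor_day[keep])[:, None]
        base = amp[anchor_day[keep], np.nonzero(keep)[0], :]
        with np.errstate(over="ignore"):
            amp[d, keep] = base * np.exp(-dt / tau_arr[None, :])

    baseline = config.baseline_fluo * (1.0 + 0.1 * rng.standard_normal(n_cells))
    baseline = np.clip(baseline, 0.5 * config.baseline_fluo, None)
    return GroundTruthTuning(
        variables=VARIABLE_NAMES,
        tuned=tuned,
        preferred=pref,
        amplitude=amp,
        tau=dict(tau_by_variable),
        kernels=make_response_kernels(config),
        baseline=baseline,
        turnover_prob=float(turnover_prob),
        retained=retained,
    )


def simulate_day_activity(
    tuning: GroundTruthTuning,
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    day: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one day's soma and neuropil fluorescence (cells x frames, a.u.).

    ``day`` is 1-based. Soma = baseline + tuned transients + alpha_true *
    (neuropil - mean) + white noise. Aborted trials carry no transients.
    """
    if not 1 <= day <= tuning.n_days:
        raise ValueError(f"day {day} outside 1..{tuning.n_days}")
    n_cells = tuning.n_cells
    tlen = config.trial_len_frames
    n_frames = tlen * len(trials)
    rng = np.random.default_rng(seed)
    d = day - 1

    # shared slow neuropil signal (low-pass-filtered Gaussian noise)
    shared = gaussian_filter1d(rng.standard_normal(n_frames), sigma=10.0, mode="reflect")
    shared *= 0.08 * config.baseline_fluo / max(shared.std(), 1e-12)
    np_baseline = 0.5 * config.baseline_fluo
    f_neuropil = np.tile(np_baseline + shared, (n_cells, 1))
    f_neuropil += 0.01 * config.baseline_fluo * rng.standard_normal(f_neuropil.shape)

    signal = np.zeros((n_cells, n_frames))
    kern = np.stack([tuning.kernels[v] for v in tuning.variables])  # (n_vars, tlen)
    amp_frac = tuning.amplitude[d] / 100.0 * tuning.baseline[:, None]  # a.u.
    for t_idx, tr in enumerate(trials):
        if tr.aborted:
            continue
        cls = np.array([CLASS_RULES[v][tr.trial_type] for v in tuning.variables])
        match = tuning.tuned[d] & (tuning.preferred[d] == cls[None, :])  # (cells, vars)
        if not match.any():
            continue
        gain = np.clip(1.0 + config.trial_gain_sd * rng.standard_normal(n_cells), 0.0, None)
        contrib = (amp_frac * match) @ kern  # (cells, tlen)
        sl = slice(t_idx * tlen, (t_idx + 1) * tlen)
        signal[:, sl] += gain[:, None] * contrib

    noise = (config.noise_sd / 100.0) * tuning.baseline[:, None] \
        * rng.standard_normal((n_cells, n_frames))
    centered_np = f_neuropil - f_neuropil.mean(axis=1, keepdims=True)
    f_soma = tuning.baseline[:, None] + signal \
        + config.neuropil_alpha_true * centered_np + noise
    return f_soma.astype(np.float64), f_neuropil.astype(np.float64)


def _render_field(base_texture: np.ndarray, centers: np.ndarray,
                  blob_amps: np.ndarray, sigma_px: float,
                  rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """One day's mean-image field: textured background + Gaussian somata."""
    fld = base_texture.copy()
    h, w = fld.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), a in zip(centers, blob_amps):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        m = r2 < (4 * sigma_px) ** 2
        fld[m] += a * np.exp(-r2[m] / (2 * sigma_px ** 2))
    if noise_sd > 0:
        fld = fld + noise_sd * rng.standard_normal(fld.shape)
    return fld


def generate_roi_patches(
    config: TaskConfig,
    n_unstable: int,
    seed: int,
    jitter_px: float = 0.5,
    noise_sd: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-day ROI patch stacks plus the field images they were cut from.

    Returns ``(patches, fields, centers, unstable)`` with shapes
    ``(n_days, n_cells, p, p)``, ``(n_days, H, W)``, ``(n_cells, 2)`` and
    ``(n_cells,)`` (bool mask of relocated cells).
    Stable cells' patches are extracted at the day-1 ROI window every day
    (small center jitter + per-day noise); unstable cells' day-k (k >= 2)
    patches are replaced by windows at a different random field location,
    emulating a lost or misregistered ROI. Set ``jitter_px = noise_sd = 0``
    for byte-identical patches across days.
    """
    if n_unstable > config.n_cells:
        raise ConfigError("n_unstable exceeds n_cells")
    rng = np.random.default_rng(seed)
    p = config.patch_size_px
    fsz = config.field_size_px
    margin = p // 2 + 2
    n_cells, n_days = config.n_cells, config.n_days

    base_texture = gaussian_filter(rng.standard_normal((fsz, fsz)), sigma=2.0)
    base_texture = 0.3 + 0.15 * (base_texture / base_texture.std())
    centers = rng.integers(margin, fsz - margin, size=(n_cells, 2))
    blob_amps = 0.6 + 0.3 * rng.random(n_cells)
    unstable = np.zeros(n_cells, dtype=bool)
    unstable[rng.choice(n_cells, size=n_unstable, replace=False)] = True

    fields = np.empty((n_days, fsz, fsz), dtype=np.float64)
    patches = np.empty((n_days, n_cells, p, p), dtype=np.float64)
    for d in range(n_days):
        blob_centers = centers.astype(float)
        if d > 0:
            blob_centers = blob_centers + jitter_px * rng.standard_normal((n_cells, 2))
        fld = _render_field(base_texture, blob_centers, blob_amps, sigma_px=2.5,
                            rng=rng, noise_sd=noise_sd if d > 0 else 0.0)
        fields[d] = fld
        extract = centers.copy()
        if d > 0 and unstable.any():
            # lost/misregistered ROI: window lands on unrelated tissue
            extract[unstable] = rng.integers(
                margin, fsz - margin, size=(int(unstable.sum()), 2))
        for i, (cy, cx) in enumerate(extract):
            y0, x0 = int(cy) - p // 2, int(cx) - p // 2
            patches[d, i] = fld[y0:y0 + p, x0:x0 + p]
    return patches, fields, centers, unstable


@dataclass
class DayData:
    """One session's raw and (optionally) derived data."""

    day: int                      # 1-based
    f_soma: np.ndarray            # (cells, frames)
    f_neuropil: np.ndarray        # (cells, frames)
    trials: List[TrialRecord]
    roi_patches: np.ndarray       # (cells, p, p)
    field: Optional[np.ndarray] = None
    dff: Optional[np.ndarray] = None      # (cells, frames), percent
    alpha: Optional[np.ndarray] = None    # (cells,)
    spikes: Optional[np.ndarray] = None   # optional precomputed inferred spikes


@dataclass
class ExperimentBundle:
    """One mouse x field recording across days, with optional ground truth."""

    days: List[DayData]
    mouse_id: int
    experiment_id: int
    frame_rate_hz: float
    ground_truth: Optional[GroundTruthTuning] = None
    unstable_cells: Optional[np.ndarray] = None

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def n_cells(self) -> int:
        return self.days[0].f_soma.shape[0]

    def validate(self) -> None:
        n_cells = self.n_cells
        for dd in self.days:
            for arr in (dd.f_soma, dd.f_neuropil):
                if arr.shape[0] != n_cells:
                    raise ValueError("cell dimension differs across days")
                if not np.isfinite(arr).all():
                    raise ValueError(f"non-finite values on day {dd.day}")
            n_frames = dd.f_soma.shape[1]
            for tr in dd.trials:
                if not (0 <= tr.start_frame and tr.reward_end_frame < n_frames):
                    raise ValueError(f"trial {tr.index} frames outside recording")


def generate_experiment(
    config: TaskConfig,
    tau_by_variable: Dict[str, float],
    seed: int,
    mouse_id: int = 0,
    experiment_id: int = 0,
    n_unstable: int = 0,
    turnover_prob: Optional[float] = None,
) -> ExperimentBundle:
    """Compose schedule, tuning, activity, and ROI patches into one bundle.

    Deterministic given ``(config, seed)``: all stage seeds are spawned
    from one ``SeedSequence``.
    """
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3 + 2 * config.n_days)
    tuning = make_drifting_tuning(config, tau_by_variable,
                                  seed=kids[0], turnover_prob=turnover_prob)
    patches, fields, _, unstable = generate_roi_patches(config, n_unstable, seed=kids[1])

    days: List[DayData] = []
    for d in range(1, config.n_days + 1):
        trials = generate_trial_schedule(config, seed=kids[1 + 2 * d])
        f_soma, f_np = simulate_day_activity(tuning, trials, config, day=d,
                                             seed=kids[2 + 2 * d])
        days.append(DayData(day=d, f_soma=f_soma, f_neuropil=f_np,
                            trials=trials, roi_patches=patches[d - 1],
                            field=fields[d - 1]))
    bundle = ExperimentBundle(days=days, mouse_id=mouse_id,
                              experiment_id=experiment_id,
                              frame_rate_hz=config.frame_rate_hz,
                              ground_truth=tuning,
                              unstable_cells=unstable)
    bundle.validate()
    return bundle
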