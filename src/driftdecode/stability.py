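"""Cross-day decay quantification: window integration, exponential fits,
rankit transform, and mixed-effects comparisons.

Three decay-model variants are fitted by bounded nonlinear least squares:

* ``cc_decay``       CC(day)  = CC_day1 * e^((1-day)/tau)
* ``perf_baseline``  P(day)   = P_day1  * e^((1-day)/tau) + 0.5
  (the 0.5 accounts for the chance-level baseline of a binary decoder)
* ``normalized``     NP(day)  = e^((1-day)/tau)           (one parameter)

NP is the decoding performance integrated above chance over the
variable's 1.5-s window, normalized by the day-1 (training-day) area, so
NP(1) = 1 by construction and the fitted curve reaches 1/e exactly one
time constant after day 1. Poor fits are discarded with the SSE <= 1.6
and R^2 > 0 filters; fit parameters are rankit-transformed before linear
mixed-effects comparisons (REML, random intercepts for mouse and
experiment, p-values floored at 1e-5).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, rankdata

__all__ = [
    "DecayFit",
    "WindowIntegral",
    "RankitValues",
    "LmeResult",
    "integrate_window",
    "normalize_performance",
    "fit_decay",
    "filter_fits",
    "rankit",
    "lme_compare",
]

TAU_BOUNDS = (0.05, 100.0)
AMP_BOUNDS = (0.0, 2.0)
TAU_STARTS = (0.5, 2.0, 8.0, 32.0)
SSE_MAX = 1.6


def integrate_window(mean_performance: np.ndarray, bin_times: np.ndarray,
                     window: Tuple[float, float]) -> float:
    """Signed area between a decoding curve and chance over a time window.

    Trapezoidal integral of (performance - 0.5) over bins sampling
    ``window`` inclusively at both ends (a constant curve integrates to
    exactly width x height); dips below chance subtract. Units:
    fraction x seconds.
    """
    perf = np.asarray(mean_performance, dtype=float)
    t = np.asarray(bin_times, dtype=float)
    t0, t1 = window
    eps = 1e-9
    mask = (t >= t0 - eps) & (t <= t1 + eps)
    if not mask.any() or t[mask].min() > t0 + eps or t[mask].max() < t1 - eps:
        raise ValueError(f"window {window} not covered by curve extent "
                         f"[{t.min()}, {t.max()}]")
    return float(np.trapezoid(perf[mask] - 0.5, t[mask]))


@dataclass
class WindowIntegral:
    variable: str
    day: int
    area: float
    np_value: Optional[float] = None  # area normalized by the day-1 area


def normalize_performance(areas_by_day: Dict[int, float],
                          train_day: int = 1) -> Tuple[Dict[int, float], bool]:
    """NP per day: area(day)/area(train day); NP(train day) = 1.

    Returns ``(np_by_day, excluded)``; a non-positive training-day area
    makes the normalization meaningless, so the series is excluded
    (empty dict, flag True).
    """
    if train_day not in areas_by_day:
        raise ValueError(f"train day {train_day} missing from areas")
    a1 = areas_by_day[train_day]
    if a1 <= 0:
        return {}, True
    return {d: a / a1 for d, a in areas_by_day.items()}, False


@dataclass
class DecayFit:
    variant: str              # cc_decay | perf_baseline | normalized
    amplitude: Optional[float]
    tau: float
    sse: float
    r2: float
    n_points: int
    converged: bool = True
    entity: str = ""

    def predict(self, day) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        decay = np.exp((1.0 - day) / self.tau)
        if self.variant == "normalized":
            return decay
        if self.variant == "cc_decay":
            return self.amplitude * decay
        return self.amplitude * decay + 0.5  # perf_baseline


_OFFSETS = {"cc_decay": 0.0, "perf_baseline": 0.5, "normalized": 0.0}


def fit_decay(values: Sequence[float], days: Sequence[float],
              variant: str = "normalized") -> DecayFit:
    """Bounded nonlinear least-squares exponential-decay fit.

    tau is constrained to (0.05, 100] days and the amplitude (where free)
    to [0, 2]; optimization multistarts from tau in {0.5, 2, 8, 32} and
    keeps the best-SSE solution. R^2 is taken relative to the mean-only
    model. The ``normalized`` variant requires >= 2 day points, the
    two-parameter variants >= 3.
    """
    if variant not in _OFFSETS:
        raise ValueError(f"unknown variant {variant!r}")
    y = np.asarray(values, dtype=float)
    d = np.asarray(days, dtype=float)
    if y.shape != d.shape or y.ndim != 1:
        raise ValueError("values and days must be equal-length 1-D")
    if not (np.isfinite(y).all() and np.isfinite(d).all()):
        raise ValueError("non-finite inputs to fit_decay")
    min_pts = 2 if variant == "normalized" else 3
    if y.size < min_pts:
        raise ValueError(f"{variant} fit needs >= {min_pts} day points")
    offset = _OFFSETS[variant]
    with_amp = variant != "normalized"

    def residuals(theta):
        if with_amp:
            amp, tau = theta
        else:
            amp, tau = 1.0, theta[0]
        return amp * np.exp((1.0 - d) / tau) + offset - y

    best = None
    amp0 = float(np.clip(y[np.argmin(d)] - offset, AMP_BOUNDS[0] + 1e-6,
                         AMP_BOUNDS[1] - 1e-6)) if with_amp else None
    for tau0 in TAU_STARTS:
        x0 = [amp0, tau0] if with_amp else [tau0]
        lb = [AMP_BOUNDS[0], TAU_BOUNDS[0]] if with_amp else [TAU_BOUNDS[0]]
        ub = [AMP_BOUNDS[1], TAU_BOUNDS[1]] if with_amp else [TAU_BOUNDS[1]]
        try:
            res = least_squares(residuals, x0=x0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return DecayFit(variant=variant, amplitude=None, tau=np.nan,
                        sse=np.inf, r2=-np.inf, n_points=y.size, converged=False)
    sse, res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse < 1e-12 else 0.0)
    if with_amp:
        amp, tau = res.x
    else:
        amp, tau = None, res.x[0]
    return DecayFit(variant=variant, amplitude=amp, tau=float(tau),
                    sse=sse, r2=r2, n_points=int(y.size), converged=True)


def filter_fits(fits: Sequence[DecayFit], sse_max: float = SSE_MAX) -> List[DecayFit]:
    """Keep fits with SSE <= 1.6 and positive R^2 (better than the mean)."""
    return [f for f in fits
            if f.converged and f.sse <= sse_max and f.r2 > 0]


@dataclass
class RankitValues:
    values: np.ndarray
    ranks: np.ndarray
    n: int
    transformed: np.ndarray


def rankit(values: Sequence[float]) -> RankitValues:
    """Inverse-normal transform of fractional ranks.

    transformed_i = invnormal((rank_i - 0.5) / n), ranks 1..n with ties
    averaged; monotone in the inputs, and the median of an odd-length
    distinct sample maps to 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rankit needs a 1-D sample of size >= 2")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in rankit input")
    r = rankdata(x, method="average")
    return RankitValues(values=x, ranks=r, n=x.size,
                        transformed=norm.ppf((r - 0.5) / x.size))


@dataclass
class LmeResult:
    response: str
    fixed_effect: str
    levels: Tuple[str, ...]
    pairwise_p: Dict[Tuple[str, str], float]
    flags: Dict[Tuple[str, str], str] = field(default_factory=dict)

P_FLOOR = 1e-5


def _fit_pair_lme(df: pd.DataFrame) -> Tuple[float, str]:
    """Two-level LME: y ~ group, random intercepts mouse + experiment (REML).

    Returns (two-sided p for the group contrast, flag). Singular
    random-effect structures are refit without the experiment component.
    """
    import statsmodels.formula.api as smf

    flag = ""
    for vcf in ({"experiment": "0 + C(experiment)"}, None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("y ~ C(group)", data=df, groups="mouse",
                                    re_formula="1", vc_formula=vcf)
                fit = model.fit(reml=True)
            p = float(fit.pvalues[[i for i in fit.pvalues.index
                                   if i.startswith("C(group)")][0]])
            if np.isfinite(p):
                return p, flag
        except Exception:
            pass
        flag = "experiment_vc_dropped"
    # last resort: plain two-sample comparison flag
    from scipy.stats import f_oneway
    p = float(f_oneway(df.loc[df.group == df.group.unique()[0], "y"],
                       df.loc[df.group == df.group.unique()[1], "y"]).pvalue)
    return p, "lme_failed_fallback_anova"


def lme_compare(
    values: Sequence[float],
    labels: Sequence[str],
    mouse_ids: Sequence,
    experiment_ids: Sequence,
    response: str = "response",
    fixed_effect: str = "variable",
) -> LmeResult:
    """Pairwise mixed-effects comparisons of a response across groups.

    For every pair of fixed-effect levels the model ``y ~ group`` with
    random intercepts for mouse and experiment (nominal) is fitted by
    REML on the subset of the two levels; the group contrast's two-sided
    p-value (Wald F-test; with one contrast F = t^2) is floored at 1e-5.
    Values should be rankit-transformed upstream where appropriate.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(labels)
    mouse = np.asarray(mouse_ids)
    exp = np.asarray(experiment_ids)
    levels = tuple(sorted(set(g.tolist())))
    if len(levels) < 2:
        raise ValueError("need >= 2 fixed-effect levels")
    out = LmeResult(response=response, fixed_effect=fixed_effect,
                    levels=levels, pairwise_p={})
    for a, b in itertools.combinations(levels, 2):
        mask = (g == a) | (g == b)
        df = pd.DataFrame({"y": y[mask], "group": g[mask],
                           "mouse": mouse[mask], "experiment": exp[mask]})
        p, flag = _fit_pair_lme(df)
        out.pairwise_p[(a, b)] = max(p, P_FLOOR)
        if flag:
            out.flags[(a, b)] = flag
    return out
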