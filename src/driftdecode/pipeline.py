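"""End-to-end orchestration: config validation, staged runs, reports.

The pipeline runs simulate/load -> preprocess -> qc -> responses ->
decode -> stability and collects machine-readable tables in a
:class:`ReportBundle`. One master seed determines every stochastic
stage (per-stage generators are spawned from ``SeedSequence([master,
stage_index])`` so stages can be rerun in isolation); every written
table carries the config hash and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as ddio
from .decoding import decode_across_days, significant_encoding
from .preprocess import align_to_trials, preprocess_day
from .qc import (check_session_inclusion, reliability_test, roi_stability_test,
                 sample_null_windows, select_cells)
from .responses import crossday_response_cc, preference_test
from .stability import (fit_decay, integrate_window, lme_compare,
                        normalize_performance, rankit)
from .synth import generate_experiment
from .task import (CORRECT_TYPES, STABILITY_WINDOWS, TRIAL_TYPES, TaskConfig,
                   VARIABLE_NAMES, ConfigError)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config",
           "run_pipeline", "write_report", "ReportBundle"]

SCHEMA_VERSION = "1"

DEFAULT_CONFIG: Dict = {
    "input": "simulate",            # "simulate" or list of bundle paths
    "n_experiments": 3,
    "experiments_per_mouse": 3,
    "seed": 0,
    "output_dir": None,
    "task": {},                     # TaskConfig overrides
    "tau_by_variable": {
        "context": 7.3,
        "motor": 1.9,
        "post_decision_outcome": 2.2,
        "post_trial_outcome": 35.7,
    },
    "windows": {k: list(v) for k, v in STABILITY_WINDOWS.items()},
    "qc": {
        "reliability_iters": 100,
        "n_null_windows": 60,
        "roi_metric": "ssim",
        "run_roi_stability": True,
    },
    "decoding": {
        "n_iter": 25,
        "C": 1.0,
        "window_only": True,
        "max_encoding_cells": 15,
        "encoding_n_iter": 20,
    },
    "stability": {
        "sse_max": 1.6,
        "run_lme": True,
        "min_fit_days": 3,
    },
}

_TASK_FIELDS = {f.name for f in dc_fields(TaskConfig)}


def _merge_section(defaults: Dict, user: Dict, path: str) -> Dict:
    out = dict(defaults)
    problems = []
    for k, v in user.items():
        if k not in defaults:
            problems.append(f"unknown key {path}{k!r}")
        else:
            out[k] = v
    if problems:
        raise ConfigError("; ".join(problems))
    return out


def load_config(path) -> Dict:
    """Read a pipeline configuration from a YAML or JSON file and validate it."""
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    return validate_config(cfg)


def validate_config(config: Optional[Dict] = None) -> Dict:
    """Fill defaults, reject unknown keys, and check units/invariants.

    All violations are collected and reported together. Stability windows
    must be exactly 1.5 s wide.
    """
    config = dict(config or {})
    problems: List[str] = []
    out = _merge_section(DEFAULT_CONFIG, config, "")
    for section in ("qc", "decoding", "stability"):
        if not isinstance(out[section], dict):
            raise ConfigError(f"{section} must be a mapping")
        out[section] = _merge_section(DEFAULT_CONFIG[section],
                                      config.get(section, {}), f"{section}.")
    task_over = config.get("task", {})
    bad_task = set(task_over) - _TASK_FIELDS
    if bad_task:
        problems.append(f"unknown task keys {sorted(bad_task)}")
    else:
        try:
            TaskConfig(**task_over)
        except ConfigError as e:
            problems.append(str(e))
    for v, tau in out["tau_by_variable"].items():
        if v not in VARIABLE_NAMES:
            problems.append(f"unknown variable {v!r} in tau_by_variable")
        elif not tau > 0:
            problems.append(f"tau for {v!r} must be > 0")
    for v, win in out["windows"].items():
        if v not in VARIABLE_NAMES:
            problems.append(f"unknown variable {v!r} in windows")
            continue
        w = float(win[1]) - float(win[0])
        if abs(w - 1.5) > 1e-9:
            problems.append(f"window for {v!r} must be 1.5 s wide, got {w} s")
    if out["input"] != "simulate":
        for p in list(out["input"]):
            if not Path(p).exists():
                problems.append(f"input path does not exist: {p}")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return out


def config_hash(config: Dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_rng(master: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), stage]))


@dataclass
class ReportBundle:
    """Machine-readable pipeline outputs (tidy DataFrames)."""

    session_inclusion: Optional[pd.DataFrame] = None
    qc_cells: Optional[pd.DataFrame] = None
    preference: Optional[pd.DataFrame] = None
    cc_fits: Optional[pd.DataFrame] = None
    encoding_calls: Optional[pd.DataFrame] = None
    decoding_curves: Optional[pd.DataFrame] = None
    np_by_day: Optional[pd.DataFrame] = None
    decay_fits: Optional[pd.DataFrame] = None
    lme_summary: Optional[pd.DataFrame] = None
    config: Dict = field(default_factory=dict)
    config_hash: str = ""
    master_seed: int = 0

    TABLE_NAMES = ("session_inclusion", "qc_cells", "preference", "cc_fits",
                   "encoding_calls", "decoding_curves", "np_by_day",
                   "decay_fits", "lme_summary")


def run_pipeline(config: Optional[Dict] = None) -> ReportBundle:
    """Execute the full analysis on simulated (or loaded) bundles."""
    cfg = validate_config(config)
    master = int(cfg["seed"])
    chash = config_hash(cfg)
    report = ReportBundle(config=cfg, config_hash=chash, master_seed=master)
    task = TaskConfig(**cfg["task"])
    fr = task.frame_rate_hz
    n_days = task.n_days

    # ---- stage 0: simulate or load -------------------------------------
    rng0 = _stage_rng(master, 0)
    bundles = []
    if cfg["input"] == "simulate":
        for e in range(int(cfg["n_experiments"])):
            seed_e = int(rng0.integers(0, 2 ** 31 - 1))
            bundles.append(generate_experiment(
                task, cfg["tau_by_variable"], seed=seed_e,
                mouse_id=e // int(cfg["experiments_per_mouse"]),
                experiment_id=e))
    else:
        bundles = [ddio.read_bundle(p) for p in cfg["input"]]
    logger.info("stage simulate/load: %d bundles", len(bundles))

    # ---- stage 1: preprocess -------------------------------------------
    tensors: Dict[int, Dict[int, Tuple[np.ndarray, np.ndarray]]] = {}
    for e, bundle in enumerate(bundles):
        tensors[e] = {}
        for dd in bundle.days:
            if dd.dff is None:
                dd.dff, dd.alpha = preprocess_day(dd.f_soma, dd.f_neuropil)
            tt = align_to_trials(dd.dff, dd.trials,
                                 window=(0.0, task.trial_duration_s),
                                 frame_rate_hz=fr, day=dd.day)
            tensors[e][dd.day] = (tt.values, tt.labels)

    # ---- stage 2: qc ----------------------------------------------------
    rng2 = _stage_rng(master, 2)
    qc_rows, sess_rows = [], []
    selections = {}
    for e, bundle in enumerate(bundles):
        n_cells = bundle.n_cells
        reliable = np.zeros((n_days, n_cells), dtype=bool)
        stable = np.ones((n_days, n_cells), dtype=bool)
        included = np.zeros(n_days, dtype=bool)
        for d_idx, dd in enumerate(bundle.days):
            si = check_session_inclusion(dd.trials)
            included[d_idx] = si.included
            sess_rows.append(dict(experiment=e, day=dd.day, n_CL=si.n_CL,
                                  n_IR=si.n_IR, n_IL=si.n_IL, n_CR=si.n_CR,
                                  performance=si.performance,
                                  min_count=si.min_count, included=si.included))
            vals, labels = tensors[e][dd.day]
            correct = np.isin(labels, list(CORRECT_TYPES))
            for c in range(n_cells):
                rel = reliability_test(vals[c][correct],
                                       n_iter=int(cfg["qc"]["reliability_iters"]),
                                       seed=int(rng2.integers(0, 2 ** 31 - 1)))
                reliable[d_idx, c] = rel.reliable
                qc_rows.append(dict(experiment=e, cell_id=c, day=dd.day,
                                    reliable=rel.reliable, cc_true=rel.cc_true,
                                    cc_threshold=rel.threshold))
        if cfg["qc"]["run_roi_stability"]:
            p1 = bundle.days[0].roi_patches
            psz = p1.shape[-1]
            for d_idx in range(1, n_days):
                dd = bundle.days[d_idx]
                for c in range(n_cells):
                    nulls = sample_null_windows(
                        dd.field, center=(dd.field.shape[0] // 2,
                                          dd.field.shape[1] // 2),
                        window_px=psz,
                        n_windows=int(cfg["qc"]["n_null_windows"]),
                        seed=int(rng2.integers(0, 2 ** 31 - 1)))
                    rs = roi_stability_test(p1[c], dd.roi_patches[c], nulls,
                                            metric=cfg["qc"]["roi_metric"])
                    stable[d_idx, c] = rs.stable
        selections[e] = select_cells(reliable, stable, included)

    report.session_inclusion = pd.DataFrame(sess_rows)
    report.qc_cells = pd.DataFrame(qc_rows)

    # ---- stage 3: responses --------------------------------------------
    rng3 = _stage_rng(master, 3)
    pref_rows, cc_rows = [], []
    groupings = ("context", "motor", "post_decision_outcome")
    for e, bundle in enumerate(bundles):
        vals1, labels1 = tensors[e][1]
        day1_cells = np.unique(np.concatenate(
            [idx for idx in selections[e].pairwise.values()] or
            [np.arange(bundle.n_cells)]))
        for c in day1_cells:
            for grouping in groupings:
                pr = preference_test(vals1[c], labels1, grouping,
                                     seed=int(rng3.integers(0, 2 ** 31 - 1)),
                                     cell_id=int(c))
                pref_rows.append(dict(
                    experiment=e, cell_id=int(c), grouping=grouping,
                    significant=pr.significant,
                    preferred_class=pr.preferred_class,
                    run_start_bin=pr.run_start_bin, run_length=pr.run_length))
        # cross-day CC by trial type, then per-cell decay fits
        cc_by_day: Dict[int, np.ndarray] = {}
        for d in range(1, n_days + 1):
            valsk, labelsk = tensors[e][d]
            cells = (np.arange(bundle.n_cells) if d == 1
                     else selections[e].pairwise.get(d, np.array([], int)))
            cc = np.full(bundle.n_cells, np.nan)
            if cells.size:
                cc[cells] = crossday_response_cc(
                    vals1[cells], labels1, valsk[cells], labelsk,
                    classes=[[t] for t in TRIAL_TYPES])
            cc_by_day[d] = cc
        for c in range(bundle.n_cells):
            series = {d: cc_by_day[d][c] for d in cc_by_day
                      if np.isfinite(cc_by_day[d][c])}
            if len(series) < int(cfg["stability"]["min_fit_days"]):
                continue
            fit = fit_decay(list(series.values()), list(series.keys()),
                            variant="cc_decay")
            cc_rows.append(dict(experiment=e, cell_id=c, variant="cc_decay",
                                amplitude=fit.amplitude, tau=fit.tau,
                                sse=fit.sse, r2=fit.r2,
                                n_points=fit.n_points,
                                retained=fit.converged and fit.sse <=
                                float(cfg["stability"]["sse_max"]) and fit.r2 > 0))
    report.preference = pd.DataFrame(pref_rows)
    report.cc_fits = pd.DataFrame(cc_rows)

    # ---- stage 4: decoding ---------------------------------------------
    rng4 = _stage_rng(master, 4)
    dec_cfg = cfg["decoding"]
    curve_rows, np_rows, fit_rows, enc_rows = [], [], [], []
    tau_fits = []
    for e, bundle in enumerate(bundles):
        for vname in VARIABLE_NAMES:
            w0, w1 = cfg["windows"][vname]
            if dec_cfg["window_only"]:
                bins = np.arange(int(round(w0 * fr)), int(round(w1 * fr)) + 1)
            else:
                bins = None
            # per (day 1, day k) pair: the day-1 reference area comes from the
            # same pair-selected cells as the day-k test, so NP is not biased
            # by unequal cell counts
            np_series: Dict[int, float] = {1: 1.0}
            areas: Dict[int, float] = {}
            vals1, labels1 = tensors[e][1]
            for d in range(2, n_days + 1):
                cells = selections[e].pairwise.get(d, np.array([], int))
                if cells.size == 0:
                    continue
                valsk, labelsk = tensors[e][d]
                within = decode_across_days(
                    vals1[cells], labels1, None, None, vname,
                    train_day=1, test_day=1, n_iter=int(dec_cfg["n_iter"]),
                    seed=int(rng4.integers(0, 2 ** 31 - 1)),
                    bins=bins, C=float(dec_cfg["C"]), bin_duration_s=1.0 / fr)
                cross = decode_across_days(
                    vals1[cells], labels1, valsk[cells], labelsk, vname,
                    train_day=1, test_day=d, n_iter=int(dec_cfg["n_iter"]),
                    seed=int(rng4.integers(0, 2 ** 31 - 1)),
                    bins=bins, C=float(dec_cfg["C"]), bin_duration_s=1.0 / fr)
                for curve in (within, cross):
                    for b, tm, mp, lo, hi in zip(
                            curve.bin_indices, curve.bin_times,
                            curve.mean_performance, curve.ci_low, curve.ci_high):
                        curve_rows.append(dict(
                            experiment=e, variable=vname,
                            unit="experiment_population", train_day=1,
                            test_day=curve.test_day, pair_day=d,
                            n_cells=int(cells.size), bin=int(b),
                            bin_time_s=float(tm), mean=float(mp),
                            ci_low=float(lo), ci_high=float(hi)))
                a1 = integrate_window(within.mean_performance,
                                      within.bin_times, (w0, w1))
                ak = integrate_window(cross.mean_performance,
                                      cross.bin_times, (w0, w1))
                areas[d] = ak
                ratio, excluded = normalize_performance({1: a1, d: ak})
                if not excluded:
                    np_series[d] = ratio[d]
            for d, npv in sorted(np_series.items()):
                np_rows.append(dict(experiment=e, variable=vname, day=d,
                                    area=areas.get(d, np.nan), np=npv))
            if len(np_series) >= 2:
                fit = fit_decay(list(np_series.values()),
                                list(np_series.keys()), variant="normalized")
                keep = (fit.converged and fit.sse <=
                        float(cfg["stability"]["sse_max"]) and fit.r2 > 0)
                fit_rows.append(dict(entity=f"exp{e}", experiment=e,
                                     mouse=bundle.mouse_id, variable=vname,
                                     variant="normalized", amplitude=np.nan,
                                     tau=fit.tau, sse=fit.sse, r2=fit.r2,
                                     retained=keep))
                if keep:
                    tau_fits.append((vname, bundle.mouse_id, e, fit.tau))
        # single-cell encoding calls on a capped subset of day-1 cells
        max_cells = int(dec_cfg["max_encoding_cells"])
        if max_cells > 0:
            vals1, labels1 = tensors[e][1]
            subset = np.arange(min(max_cells, bundle.n_cells))
            end_bin = task.trial_end_offset
            for c in subset:
                for vname in ("context", "motor", "post_decision_outcome"):
                    curve = decode_across_days(
                        vals1[c][None], labels1, None, None, vname,
                        unit="single_cell",
                        n_iter=int(dec_cfg["encoding_n_iter"]),
                        seed=int(rng4.integers(0, 2 ** 31 - 1)),
                        C=float(dec_cfg["C"]), bin_duration_s=1.0 / fr)
                    for call in significant_encoding(curve, trial_end_bin=end_bin):
                        enc_rows.append(dict(
                            experiment=e, cell_id=int(c), tested=vname,
                            significant=call.significant,
                            assigned_variable=call.assigned_variable,
                            run_start=None if call.qualifying_run is None
                            else call.qualifying_run[0],
                            run_length=None if call.qualifying_run is None
                            else call.qualifying_run[1]))
    report.decoding_curves = pd.DataFrame(curve_rows)
    report.np_by_day = pd.DataFrame(np_rows)
    report.decay_fits = pd.DataFrame(fit_rows)
    report.encoding_calls = pd.DataFrame(enc_rows)

    # ---- stage 5: stability LME ----------------------------------------
    if cfg["stability"]["run_lme"] and tau_fits:
        df = pd.DataFrame(tau_fits, columns=["variable", "mouse", "experiment",
                                             "tau"])
        lme_rows = []
        if df["variable"].nunique() >= 2 and len(df) >= 4:
            try:
                rk = rankit(df["tau"].to_numpy()).transformed
                res = lme_compare(rk, df["variable"], df["mouse"],
                                  df["experiment"], response="tau")
                for (a, b), p in res.pairwise_p.items():
                    lme_rows.append(dict(response="tau", level_a=a, level_b=b,
                                         p=p, flag=res.flags.get((a, b), "")))
            except Exception as err:  # small-sample LME may fail; report it
                logger.warning("stage stability: LME failed (%s)", err)
                lme_rows.append(dict(response="tau", level_a="", level_b="",
                                     p=np.nan, flag=f"failed: {err}"))
        report.lme_summary = pd.DataFrame(lme_rows) if lme_rows else None

    if cfg["output_dir"]:
        write_report(report, cfg["output_dir"])
    return report


def write_report(report: ReportBundle, outdir) -> List[Dict]:
    """Write the report tables as CSV plus a checksum manifest.

    Every table gains ``config_hash`` and ``master_seed`` columns; a
    missing table is marked absent in the manifest rather than failing.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name in ReportBundle.TABLE_NAMES:
        df = getattr(report, name)
        entry = {"file": f"{name}.csv", "schema_version": SCHEMA_VERSION}
        if df is None:
            entry["absent"] = True
            entry["checksum"] = None
        else:
            df = df.copy()
            df["config_hash"] = report.config_hash
            df["master_seed"] = report.master_seed
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            entry["absent"] = False
            entry["checksum"] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest.append(entry)
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(
        {"config": report.config, "config_hash": report.config_hash,
         "master_seed": report.master_seed}, indent=2, sort_keys=True,
        default=str))
    manifest.append({"file": "config.json", "schema_version": SCHEMA_VERSION,
                     "absent": False,
                     "checksum": hashlib.sha256(cfg_path.read_bytes()).hexdigest()})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
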