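"""HDF5 experiment-bundle and CSV trial-table I/O.

One HDF5 file per experiment: groups ``/day{d}/`` holding ``f_soma`` and
``f_neuropil`` (cells x frames, float32), ``roi_patches``, the ``trials``
table, optionally ``field``, ``dff`` and ``alpha``; ``/meta`` attributes
(mouse_id, experiment_id, frame_rate_hz) and a ``/ground_truth`` group
when the bundle is synthetic. Frames are 0-based; windows are half-open
in seconds relative to trial start.
"""

from __future__ import annotations

from typing import List

import h5py
import numpy as np
import pandas as pd

from .synth import DayData, ExperimentBundle, GroundTruthTuning
from .task import TrialRecord

__all__ = [
    "write_bundle",
    "read_bundle",
    "trials_to_dataframe",
    "trials_from_dataframe",
]

TRIAL_COLUMNS = ["index", "context", "choice", "outcome", "trial_type",
                 "start_frame", "decision_frame", "end_frame", "reward_end_frame"]

_TRIAL_DTYPE = np.dtype([
    ("index", "<i8"), ("context", "<i8"), ("choice", "S8"), ("outcome", "S12"),
    ("trial_type", "S8"), ("start_frame", "<i8"), ("decision_frame", "<i8"),
    ("end_frame", "<i8"), ("reward_end_frame", "<i8"),
])


def trials_to_dataframe(trials: List[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in TRIAL_COLUMNS} for t in trials],
                        columns=TRIAL_COLUMNS)


def trials_from_dataframe(df: pd.DataFrame) -> List[TrialRecord]:
    return [TrialRecord(**{c: (int(row[c]) if c not in
                               ("choice", "outcome", "trial_type") else str(row[c]))
                           for c in TRIAL_COLUMNS})
            for _, row in df.iterrows()]


def _trials_to_records(trials: List[TrialRecord]) -> np.ndarray:
    arr = np.empty(len(trials), dtype=_TRIAL_DTYPE)
    for i, t in enumerate(trials):
        arr[i] = (t.index, t.context, t.choice.encode(), t.outcome.encode(),
                  t.trial_type.encode(), t.start_frame, t.decision_frame,
                  t.end_frame, t.reward_end_frame)
    return arr


def _trials_from_records(arr: np.ndarray) -> List[TrialRecord]:
    return [TrialRecord(index=int(r["index"]), context=int(r["context"]),
                        choice=r["choice"].decode(), outcome=r["outcome"].decode(),
                        trial_type=r["trial_type"].decode(),
                        start_frame=int(r["start_frame"]),
                        decision_frame=int(r["decision_frame"]),
                        end_frame=int(r["end_frame"]),
                        reward_end_frame=int(r["reward_end_frame"]))
            for r in arr]


def write_bundle(bundle: ExperimentBundle, path: str) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["mouse_id"] = bundle.mouse_id
        meta.attrs["experiment_id"] = bundle.experiment_id
        meta.attrs["frame_rate_hz"] = bundle.frame_rate_hz
        for dd in bundle.days:
            g = f.create_group(f"day{dd.day}")
            g.create_dataset("f_soma", data=dd.f_soma.astype(np.float32))
            g.create_dataset("f_neuropil", data=dd.f_neuropil.astype(np.float32))
            g.create_dataset("roi_patches", data=dd.roi_patches.astype(np.float32))
            g.create_dataset("trials", data=_trials_to_records(dd.trials))
            if dd.field is not None:
                g.create_dataset("field", data=dd.field.astype(np.float32))
            if dd.dff is not None:
                g.create_dataset("dff", data=dd.dff.astype(np.float32))
            if dd.alpha is not None:
                g.create_dataset("alpha", data=np.asarray(dd.alpha, np.float32))
            if dd.spikes is not None:
                g.create_dataset("spikes", data=dd.spikes.astype(np.float32))
        gt = bundle.ground_truth
        if gt is not None:
            g = f.create_group("ground_truth")
            g.attrs["variables"] = [v.encode() for v in gt.variables]
            g.attrs["turnover_prob"] = gt.turnover_prob
            g.create_dataset("tuned", data=gt.tuned)
            g.create_dataset("preferred", data=gt.preferred)
            g.create_dataset("amplitude", data=gt.amplitude)
            g.create_dataset("baseline", data=gt.baseline)
            g.create_dataset("retained", data=gt.retained)
            g.create_dataset("tau", data=np.array([gt.tau.get(v, np.inf)
                                                   for v in gt.variables]))
            kg = g.create_group("kernels")
            for v in gt.variables:
                kg.create_dataset(v, data=gt.kernels[v])
        if bundle.unstable_cells is not None:
            f.create_dataset("unstable_cells", data=bundle.unstable_cells)


def read_bundle(path: str) -> ExperimentBundle:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        day_keys = sorted((k for k in f if k.startswith("day")),
                          key=lambda k: int(k[3:]))
        days = []
        for k in day_keys:
            g = f[k]
            days.append(DayData(
                day=int(k[3:]),
                f_soma=g["f_soma"][...].astype(np.float64),
                f_neuropil=g["f_neuropil"][...].astype(np.float64),
                trials=_trials_from_records(g["trials"][...]),
                roi_patches=g["roi_patches"][...].astype(np.float64),
                field=g["field"][...].astype(np.float64) if "field" in g else None,
                dff=g["dff"][...].astype(np.float64) if "dff" in g else None,
                alpha=g["alpha"][...].astype(np.float64) if "alpha" in g else None,
                spikes=g["spikes"][...].astype(np.float64) if "spikes" in g else None,
            ))
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            variables = tuple(v.decode() if isinstance(v, bytes) else str(v)
                              for v in g.attrs["variables"])
            tau_vals = g["tau"][...]
            gt = GroundTruthTuning(
                variables=variables,
                tuned=g["tuned"][...].astype(bool),
                preferred=g["preferred"][...].astype(np.int8),
                amplitude=g["amplitude"][...],
                tau={v: float(t) for v, t in zip(variables, tau_vals)},
                kernels={v: g["kernels"][v][...] for v in variables},
                baseline=g["baseline"][...],
                turnover_prob=float(g.attrs["turnover_prob"]),
                retained=g["retained"][...].astype(bool),
            )
        unstable = (f["unstable_cells"][...].astype(bool)
                    if "unstable_cells" in f else None)
        return ExperimentBundle(
            days=days, mouse_id=int(meta["mouse_id"]),
            experiment_id=int(meta["experiment_id"]),
            frame_rate_hz=float(meta["frame_rate_hz"]),
            ground_truth=gt, unstable_cells=unstable)
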