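"""Task structure: trial records and behavioral schedule generation.

The task is a two-context virtual T-maze. Each trial has three 3-s
segments at 10 Hz: start→decision (maze approach under one of two wall
patterns), decision→end (traversal of the chosen arm), and a post-trial
reward/timeout period. Context 1 rewards a left turn, context 2 a right
turn, giving four non-aborted trial types:

    (context 1, left)  -> CL   correct left
    (context 1, right) -> IR   incorrect right
    (context 2, left)  -> IL   incorrect left
    (context 2, right) -> CR   correct right

The schedule generator reproduces two behavioral constraints of the task
program: an anti-repeat ramp (the probability of repeating the displayed
context falls linearly from 50% toward 0% over `anti_repeat_span`
consecutive repeats) and a bias gate (when one response side exceeds
double the other within a `bias_window`-trial window, the context
rewarding the non-preferred side is shown until the bias clears).
Behavior is simulated by an agent that chooses the rewarded side with
probability `target_performance`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = [
    "ConfigError",
    "TaskConfig",
    "TrialRecord",
    "trial_type_of",
    "generate_trial_schedule",
    "TRIAL_TYPES",
    "CORRECT_TYPES",
]

TRIAL_TYPES = ("CL", "IR", "IL", "CR")
CORRECT_TYPES = frozenset({"CL", "CR"})

#: task variables decodable from the trial table, and the binary class each
#: trial type belongs to under each variable's partition
VARIABLE_NAMES = ("context", "motor", "post_decision_outcome", "post_trial_outcome")
_OUTCOME_RULE = {"CL": 0, "CR": 0, "IR": 1, "IL": 1}
CLASS_RULES = {
    "context": {"CL": 0, "IR": 0, "IL": 1, "CR": 1},
    "motor": {"CL": 0, "IL": 0, "IR": 1, "CR": 1},     # 0 = left, 1 = right
    "post_decision_outcome": dict(_OUTCOME_RULE),      # 0 = correct (rewarded)
    "post_trial_outcome": dict(_OUTCOME_RULE),
}
#: 1.5-s windows (s from trial start) used for stability integration
STABILITY_WINDOWS = {
    "context": (1.5, 3.0),
    "motor": (3.0, 4.5),
    "post_decision_outcome": (3.0, 4.5),
    "post_trial_outcome": (6.0, 7.5),
}
#: canonical response-kernel support per variable (s from trial start)
KERNEL_SUPPORT = {
    "context": (0.0, 6.0),
    "motor": (3.0, 4.5),
    "post_decision_outcome": (3.0, 4.5),
    "post_trial_outcome": (6.0, 7.5),
}

_TYPE_FROM_CONTEXT_CHOICE = {
    (1, "left"): "CL",
    (1, "right"): "IR",
    (2, "left"): "IL",
    (2, "right"): "CR",
}

#: rewarded (correct) side per context
_CORRECT_SIDE = {1: "left", 2: "right"}
#: context whose reward is on the given side
_CONTEXT_REWARDING = {"left": 1, "right": 2}


class ConfigError(ValueError):
    """Invalid task or pipeline configuration."""


def trial_type_of(context: int, choice: str) -> str:
    """Deterministic trial-type label from (context, choice).

    Aborted trials (``choice == "none"``) map to ``"aborted"``.
    """
    if choice == "none":
        return "aborted"
    try:
        return _TYPE_FROM_CONTEXT_CHOICE[(context, choice)]
    except KeyError:
        raise ValueError(f"invalid (context, choice) = ({context!r}, {choice!r})")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the simulated task and imaging world.

    Durations are seconds, the frame rate Hz; the trial length in frames
    is exactly ``frame_rate_hz * (pre + post + post_trial)``. Amplitude-
    like quantities (``noise_sd``) are ΔF/F percent referred to the
    baseline fluorescence.
    """

    frame_rate_hz: float = 10.0
    pre_decision_s: float = 3.0
    post_decision_s: float = 3.0
    post_trial_s: float = 3.0
    n_trials: int = 60
    n_days: int = 5
    target_performance: float = 0.74
    anti_repeat_span: int = 10
    bias_window: int = 10
    abort_rate: float = 0.02
    n_cells: int = 150
    noise_sd: float = 15.0
    neuropil_alpha_true: float = 0.7
    baseline_fluo: float = 100.0
    calcium_tau_s: float = 0.7
    trial_gain_sd: float = 0.3
    tuned_fraction: float = 0.3
    amplitude_mean: float = 8.0
    amplitude_shape: float = 6.0
    turnover_prob: float = 0.1
    patch_size_px: int = 30
    field_size_px: int = 200

    def __post_init__(self) -> None:
        positive = {
            "frame_rate_hz": self.frame_rate_hz,
            "pre_decision_s": self.pre_decision_s,
            "post_decision_s": self.post_decision_s,
            "post_trial_s": self.post_trial_s,
            "n_trials": self.n_trials,
            "n_days": self.n_days,
            "anti_repeat_span": self.anti_repeat_span,
            "bias_window": self.bias_window,
            "n_cells": self.n_cells,
            "baseline_fluo": self.baseline_fluo,
            "calcium_tau_s": self.calcium_tau_s,
            "patch_size_px": self.patch_size_px,
            "field_size_px": self.field_size_px,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigError(f"{name} must be finite and > 0, got {value!r}")
        for name, value in (("noise_sd", self.noise_sd),
                            ("abort_rate", self.abort_rate),
                            ("trial_gain_sd", self.trial_gain_sd),
                            ("amplitude_mean", self.amplitude_mean)):
            if not np.isfinite(value) or value < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {value!r}")
        if not np.isfinite(self.amplitude_shape) or self.amplitude_shape <= 0:
            raise ConfigError("amplitude_shape must be finite and > 0")
        if not 0.5 <= self.target_performance <= 1.0:
            raise ConfigError(
                f"target_performance must be in [0.5, 1], got {self.target_performance!r}")
        if not 0.0 <= self.neuropil_alpha_true <= 1.0:
            raise ConfigError("neuropil_alpha_true must be in [0, 1]")
        if not 0.0 <= self.turnover_prob <= 1.0:
            raise ConfigError("turnover_prob must be in [0, 1]")
        if not 0.0 <= self.tuned_fraction <= 1.0:
            raise ConfigError("tuned_fraction must be in [0, 1]")
        if self.patch_size_px < 8:
            raise ConfigError("patch_size_px must be >= 8")

    @property
    def trial_duration_s(self) -> float:
        return self.pre_decision_s + self.post_decision_s + self.post_trial_s

    @property
    def trial_len_frames(self) -> int:
        n = self.frame_rate_hz * self.trial_duration_s
        return int(round(n))

    @property
    def frames_per_day(self) -> int:
        return self.trial_len_frames * self.n_trials

    @property
    def decision_offset(self) -> int:
        return int(round(self.frame_rate_hz * self.pre_decision_s))

    @property
    def trial_end_offset(self) -> int:
        return int(round(self.frame_rate_hz * (self.pre_decision_s + self.post_decision_s)))


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the schedule; frame indices are 0-based and inclusive."""

    index: int
    context: int
    choice: str           # "left" | "right" | "none"
    outcome: str          # "correct" | "incorrect" | "aborted"
    trial_type: str       # "CL" | "IR" | "IL" | "CR" | "aborted"
    start_frame: int
    decision_frame: int
    end_frame: int
    reward_end_frame: int

    def __post_init__(self) -> None:
        expected = trial_type_of(self.context, self.choice)
        if expected != self.trial_type:
            raise ValueError(
                f"trial_type {self.trial_type!r} inconsistent with "
                f"(context={self.context}, choice={self.choice!r})")
        if self.choice == "none" and self.outcome != "aborted":
            raise ValueError("aborted trials must have outcome='aborted'")
        if self.choice != "none":
            expected_outcome = "correct" if self.trial_type in CORRECT_TYPES else "incorrect"
            if self.outcome != expected_outcome:
                raise ValueError(
                    f"outcome {self.outcome!r} inconsistent with type {self.trial_type!r}")
        if not (self.start_frame < self.decision_frame < self.end_frame
                <= self.reward_end_frame):
            raise ValueError("frame landmarks must satisfy start < decision < end <= reward_end")

    @property
    def aborted(self) -> bool:
        return self.choice == "none"


def _repeat_probability(run_length: int, span: int) -> float:
    # linear ramp: 0.45 after one presentation, 0 after `span` repeats
    return max(0.0, 0.5 * (1.0 - run_length / span))


def generate_trial_schedule(config: TaskConfig, seed: int) -> List[TrialRecord]:
    """Simulate one session's trial schedule and behavior.

    Returns exactly ``config.n_trials`` records laid out contiguously in
    frames (each trial occupies ``trial_len_frames`` frames; consecutive
    trial start = previous reward_end + 1).
    """
    rng = np.random.default_rng(seed)
    tlen = config.trial_len_frames
    d_off = config.decision_offset
    e_off = config.trial_end_offset

    records: List[TrialRecord] = []
    contexts: List[int] = []
    choices: List[str] = []        # non-aborted choices, trial-ordered
    gated_side: str | None = None  # side currently being countered

    for i in range(config.n_trials):
        recent = [c for c in choices[-config.bias_window:]]
        n_left = recent.count("left")
        n_right = recent.count("right")

        if gated_side is not None:
            # gate clears once the bias drops back below threshold
            if (gated_side == "left" and n_left <= 2 * n_right) or \
               (gated_side == "right" and n_right <= 2 * n_left):
                gated_side = None
        if gated_side is None:
            if n_left > 2 * n_right and n_left + n_right > 0:
                gated_side = "left"
            elif n_right > 2 * n_left and n_left + n_right > 0:
                gated_side = "right"

        if gated_side is not None:
            # show the context whose reward is on the non-preferred side
            nonpreferred = "right" if gated_side == "left" else "left"
            context = _CONTEXT_REWARDING[nonpreferred]
        elif not contexts:
            context = int(rng.integers(1, 3))
        else:
            run = 1
            while run < len(contexts) and contexts[-run - 1] == contexts[-1]:
                run += 1
            p_rep = _repeat_probability(run, config.anti_repeat_span)
            context = contexts[-1] if rng.random() < p_rep else 3 - contexts[-1]
        contexts.append(context)

        if rng.random() < config.abort_rate:
            choice, outcome = "none", "aborted"
        else:
            correct_side = _CORRECT_SIDE[context]
            if rng.random() < config.target_performance:
                choice = correct_side
            else:
                choice = "right" if correct_side == "left" else "left"
            outcome = "correct" if choice == correct_side else "incorrect"
            choices.append(choice)

        start = i * tlen
        records.append(TrialRecord(
            index=i,
            context=context,
            choice=choice,
            outcome=outcome,
            trial_type=trial_type_of(context, choice),
            start_frame=start,
            decision_frame=start + d_off,
            end_frame=start + e_off,
            reward_end_frame=start + tlen - 1,
        ))
    return records
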