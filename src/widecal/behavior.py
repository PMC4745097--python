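"""Trace-conditioning trial structure and eyelid-based trial scoring.

The task pairs a 350 ms tone (CS) with a 100 ms air puff (US) separated by a
250 ms stimulus-free trace interval, so the puff starts 600 ms after tone
onset.  Trials repeat with a randomized 31–36 s inter-trial interval.  A
trial is scored correct when the eyelid-reflection trace crosses a
baseline-derived threshold during the 600 ms between tone onset and puff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TONE_DURATION_S = 0.350
TRACE_INTERVAL_S = 0.250
PUFF_DURATION_S = 0.100
CS_US_INTERVAL_S = TONE_DURATION_S + TRACE_INTERVAL_S  # tone onset -> puff onset


@dataclass
class TrialTable:
    """Per-trial tone/puff onsets and outcomes."""

    tone_onset_s: np.ndarray
    outcome: np.ndarray  # "correct" | "incorrect" | "unscored"
    tone_duration_s: float = TONE_DURATION_S
    trace_interval_s: float = TRACE_INTERVAL_S
    puff_duration_s: float = PUFF_DURATION_S

    def __post_init__(self) -> None:
        self.tone_onset_s = np.asarray(self.tone_onset_s, dtype=np.float64)
        self.outcome = np.asarray(self.outcome, dtype=object)
        if len(self.tone_onset_s) != len(self.outcome):
            raise ValueError("tone_onset_s and outcome must have equal length")
        if np.any(np.diff(self.tone_onset_s) <= 0):
            raise ValueError("tone onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.tone_onset_s)

    @property
    def puff_onset_s(self) -> np.ndarray:
        return self.tone_onset_s + self.tone_duration_s + self.trace_interval_s

    def with_outcomes(self, outcomes: Sequence[str]) -> "TrialTable":
        return replace(self, outcome=np.asarray(list(outcomes), dtype=object))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "tone_onset_s": self.tone_onset_s,
                "puff_onset_s": self.puff_onset_s,
                "outcome": self.outcome,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        df = pd.read_csv(path)
        return cls(
            tone_onset_s=df["tone_onset_s"].to_numpy(),
            outcome=df["outcome"].to_numpy(dtype=object),
        )


@dataclass
class EyelidTrace:
    """Scalar eyelid-reflection signal sampled at the frame rate."""

    reflection: np.ndarray
    frame_rate: float = 20.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.reflection = np.asarray(self.reflection, dtype=np.float64)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def sample_index(self, t: float) -> int:
        return int(np.floor((t - self.t0) * self.frame_rate + 1e-9))

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in the half-open interval [t_start, t_end)."""
        i0 = self.sample_index(t_start)
        i1 = self.sample_index(t_end)
        if i0 < 0 or i1 > len(self.reflection):
            raise ValueError("requested window outside the recorded trace")
        return self.reflection[i0:i1]

    def to_dataframe(self) -> pd.DataFrame:
        t = self.t0 + np.arange(len(self.reflection)) / self.frame_rate
        return pd.DataFrame(
            {"frame": np.arange(len(self.reflection)), "time_s": t, "reflection": self.reflection}
        )


@dataclass
class BehaviorParams:
    baseline_window_s: float = 3.0  # pre-tone
    response_window_s: float = 0.600  # post-tone, pre-puff
    threshold_k: float = 4.0  # SD multiplier on the baseline

    def __post_init__(self) -> None:
        if self.response_window_s > CS_US_INTERVAL_S + 1e-12:
            raise ValueError("response window must end before the puff")
        if self.baseline_window_s <= 0 or self.threshold_k < 0:
            raise ValueError("invalid behavior parameters")


def generate_trial_schedule(
    n_trials: int,
    iti_range_s: tuple[float, float] = (31.0, 36.0),
    seed: int | np.random.Generator | None = None,
    start_offset_s: float = 10.0,
) -> TrialTable:
    """Random trial schedule with uniform ITIs; deterministic per seed."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    itis = rng.uniform(iti_range_s[0], iti_range_s[1], size=n_trials - 1)
    onsets = start_offset_s + np.concatenate([[0.0], np.cumsum(itis)])
    return TrialTable(tone_onset_s=onsets, outcome=np.array(["unscored"] * n_trials, dtype=object))


def classify_trial(
    eyelid: EyelidTrace, tone_onset_s: float, params: BehaviorParams | None = None
) -> str:
    """Score one trial from the eyelid trace.

    Baseline mean and SD come from the 3 s immediately pre-tone; the trial is
    correct iff any sample in [tone, tone + 600 ms) exceeds
    mean + threshold_k·SD.  With a perfectly flat baseline (SD = 0) the rule
    degenerates to "any sample above the baseline mean".
    """
    params = params or BehaviorParams()
    baseline = eyelid.window(tone_onset_s - params.baseline_window_s, tone_onset_s)
    response = eyelid.window(tone_onset_s, tone_onset_s + params.response_window_s)
    mu = baseline.mean()
    sigma = baseline.std()
    threshold = mu + params.threshold_k * sigma
    if sigma == 0:
        return "correct" if np.any(response > mu) else "incorrect"
    return "correct" if np.any(response > threshold) else "incorrect"


def classify_trials(
    eyelid: EyelidTrace, trials: TrialTable, params: BehaviorParams | None = None
) -> TrialTable:
    outcomes = [classify_trial(eyelid, t, params) for t in trials.tone_onset_s]
    return trials.with_outcomes(outcomes)


def performance_percent(trials: TrialTable) -> float:
    """100 · correct / (correct + incorrect), one decimal."""
    n_correct = int(np.sum(trials.outcome == "correct"))
    n_incorrect = int(np.sum(trials.outcome == "incorrect"))
    scored = n_correct + n_incorrect
    if scored == 0:
        raise ValueError("no scored trials")
    if scored != trials.n_trials:
        raise ValueError("all trials must be scored before computing performance")
    return round(100.0 * n_correct / scored, 1)
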