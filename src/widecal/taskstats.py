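"""Trial-aligned task-modulation statistics for ROI traces.

Each ROI's Δf trace is aligned to tone onset; the area under the trace in
the 2 s pre-tone (baseline) and 2 s post-tone (task) windows is compared
across correct trials with a paired two-sided t-test.  ROIs with p < α are
task relevant: positively modulated when the mean task-window area exceeds
the baseline area, negatively when smaller.  Latency to peak is read off the
trial-averaged response within an 8 s post-tone window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .behavior import TrialTable


@dataclass
class AnalysisParams:
    baseline_window_s: tuple[float, float] = (-2.0, 0.0)  # relative to tone
    task_window_s: tuple[float, float] = (0.0, 2.0)
    alpha: float = 0.05
    latency_window_s: tuple[float, float] = (0.0, 8.0)
    percent_decimals: int = 2
    fdr: bool = False  # optional Benjamini-Hochberg across ROIs

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        b0, b1 = self.baseline_window_s
        t0, t1 = self.task_window_s
        if b1 > t0:
            raise ValueError("baseline and task windows must not overlap")


@dataclass
class ModulationResult:
    baseline_auc: np.ndarray  # per correct trial
    task_auc: np.ndarray
    t_stat: float
    p_value: float
    label: str  # positive | negative | none
    mean_task_minus_baseline: float
    exact_difference: bool = False  # zero-variance, nonzero-mean degenerate case


@dataclass
class LatencyResult:
    latency_s: float
    peak_value: float


def align_trials(
    trace: np.ndarray,
    trials: TrialTable | Sequence[float],
    window_s: tuple[float, float],
    frame_rate: float,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a trace into a trials × samples matrix around tone onsets.

    Columns are samples at the frame rate covering the half-open window
    ``[window_s[0], window_s[1])`` relative to each tone onset.  Trials whose
    window falls outside the recording are excluded with a warning.

    Returns (matrix, included_trial_indices).
    """
    trace = np.asarray(trace, dtype=np.float64)
    onsets = trials.tone_onset_s if isinstance(trials, TrialTable) else np.asarray(trials)
    w0, w1 = window_s
    n_samp = int(round((w1 - w0) * frame_rate))
    rows = []
    included = []
    for k, tone in enumerate(onsets):
        start = int(np.floor((tone + w0 - t0) * frame_rate + 1e-9))
        stop = start + n_samp
        if start < 0 or stop > len(trace):
            warnings.warn(f"trial {k} window truncated by recording bounds; excluded")
            continue
        rows.append(trace[start:stop])
        included.append(k)
    matrix = np.vstack(rows) if rows else np.empty((0, n_samp))
    return matrix, np.asarray(included, dtype=np.int64)


def window_auc(
    aligned_row: np.ndarray,
    window_s: tuple[float, float],
    aligned_window_s: tuple[float, float],
    frame_rate: float,
) -> float:
    """Rectangle-rule area of one aligned row over a sub-window.

    ``aligned_window_s`` is the window the row was aligned with; the
    requested ``window_s`` must lie inside it.
    """
    w0, w1 = aligned_window_s
    s0, s1 = window_s
    if s0 < w0 - 1e-9 or s1 > w1 + 1e-9:
        raise ValueError("requested window outside aligned range")
    i0 = int(round((s0 - w0) * frame_rate))
    i1 = int(round((s1 - w0) * frame_rate))
    return float(np.sum(aligned_row[i0:i1]) / frame_rate)


def paired_t_pvalue(diffs: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired t-test on per-trial differences.

    Returns (t, p, exact_difference).  A zero-variance nonzero-mean
    difference vector is treated as p = 0 with the exact-difference flag
    set; an all-zero vector gives p = 1.
    """
    diffs = np.asarray(diffs, dtype=np.float64)
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, False
        return np.inf if mean > 0 else -np.inf, 0.0, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def classify_modulation(
    aligned: np.ndarray,
    correct_rows: Sequence[int],
    params: AnalysisParams | None = None,
    frame_rate: float = 20.0,
    aligned_window_s: tuple[float, float] | None = None,
) -> ModulationResult:
    """Classify one ROI's task modulation from its aligned matrix.

    ``aligned`` must cover both analysis windows; ``correct_rows`` selects
    the correct trials (the only ones entering the test).
    """
    params = params or AnalysisParams()
    if aligned_window_s is None:
        aligned_window_s = (params.baseline_window_s[0], params.task_window_s[1])
    correct_rows = np.asarray(correct_rows, dtype=np.int64)
    if len(correct_rows) < 2:
        raise ValueError("need at least 2 correct trials")
    sub = aligned[correct_rows]
    b_auc = np.array(
        [window_auc(r, params.baseline_window_s, aligned_window_s, frame_rate) for r in sub]
    )
    t_auc = np.array(
        [window_auc(r, params.task_window_s, aligned_window_s, frame_rate) for r in sub]
    )
    t, p, exact = paired_t_pvalue(t_auc - b_auc)
    mean_diff = float((t_auc - b_auc).mean())
    if p < params.alpha and mean_diff != 0:
        label = "positive" if mean_diff > 0 else "negative"
    else:
        label = "none"
    return ModulationResult(
        baseline_auc=b_auc,
        task_auc=t_auc,
        t_stat=t,
        p_value=p,
        label=label,
        mean_task_minus_baseline=mean_diff,
        exact_difference=exact,
    )


def latency_to_peak(
    aligned: np.ndarray,
    correct_rows: Sequence[int],
    params: AnalysisParams | None = None,
    frame_rate: float = 20.0,
    aligned_window_s: tuple[float, float] | None = None,
) -> LatencyResult:
    """Latency of the first maximum of the trial-averaged response.

    The average over correct trials is searched within the latency window
    (default 0–8 s post-tone); exact ties take the earliest sample.
    """
    params = params or AnalysisParams()
    if aligned_window_s is None:
        aligned_window_s = (params.baseline_window_s[0], params.latency_window_s[1])
    correct_rows = np.asarray(correct_rows, dtype=np.int64)
    avg = aligned[correct_rows].mean(axis=0)
    w0 = aligned_window_s[0]
    l0, l1 = params.latency_window_s
    i0 = int(round((l0 - w0) * frame_rate))
    i1 = min(int(round((l1 - w0) * frame_rate)) + 1, len(avg))
    seg = avg[i0:i1]
    k = int(np.argmax(seg))  # first occurrence on ties
    return LatencyResult(latency_s=l0 + k / frame_rate, peak_value=float(seg[k]))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing control)."""
    p = np.asarray(p_values, dtype=np.float64)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def classify_all(
    dff: np.ndarray,
    trials: TrialTable,
    params: AnalysisParams | None = None,
    frame_rate: float = 20.0,
    t0: float = 0.0,
) -> list[ModulationResult]:
    """Run classify_modulation for every ROI of a dff matrix.

    Alignment covers baseline through task window; trials excluded by
    alignment truncation are dropped consistently for all ROIs.
    """
    params = params or AnalysisParams()
    window = (params.baseline_window_s[0], params.task_window_s[1])
    _, included = align_trials(dff[0], trials, window, frame_rate, t0)
    outcomes = np.asarray(trials.outcome)[included]
    correct_rows = np.nonzero(outcomes == "correct")[0]
    results = []
    for row in dff:
        aligned, _ = align_trials(row, trials, window, frame_rate, t0)
        results.append(
            classify_modulation(aligned, correct_rows, params, frame_rate, window)
        )
    if params.fdr:
        adj = benjamini_hochberg(np.array([r.p_value for r in results]))
        for r, q in zip(results, adj):
            r.p_value = float(q)
            if r.p_value >= params.alpha:
                r.label = "none"
    return results


def _round_half_away(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def summarize_population(
    labels: Sequence[str], percent_decimals: int = 2
) -> dict[str, dict[str, float]]:
    """Counts and percentages of each modulation label.

    Percentages are rounded half-away-from-zero to ``percent_decimals``.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    total = len(labels)
    out: dict[str, dict[str, float]] = {"total": {"count": total, "percent": 100.0}}
    for lab in ("positive", "negative", "none"):
        count = sum(1 for x in labels if x == lab)
        out[lab] = {
            "count": count,
            "percent": _round_half_away(100.0 * count / total, percent_decimals),
        }
    return out
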