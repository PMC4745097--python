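"""Synthetic wide-field CA1 movie generator with known ground truth.

The simulator emulates a single-photon epifluorescence recording of the CA1
pyramidal layer: ~15 µm somata on a 1.312 µm/px grid, GCaMP6f-like
transients (fast rise, sub-second decay), a multiplicative illumination
vignette, rigid respiratory motion at a few Hz with rare large biphasic
jumps, slow exponential photobleaching, and sensor noise (Gaussian read
noise plus a Gaussian shot-noise approximation with variance equal to the
signal).  A 40-trial trace-conditioning schedule drives positively and
negatively task-modulated cells, and an eyelid-reflection trace is rendered
consistently with the planted trial outcomes.

All randomness flows from one seed through independent per-component
sub-streams (placement, events, motion, noise, schedule, labels, eyelid), so
changing one component's parameters does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior import CS_US_INTERVAL_S, EyelidTrace, TrialTable, generate_trial_schedule
from .preprocess import apply_shift
from .traces import TraceMatrix
from .video import VideoSequence


@dataclass
class SimParams:
    """Simulation conditions.  Defaults describe the desk-scale session:
    a 512×512 movie at 20 Hz and 1.312 µm/px (so size thresholds transfer to
    full 1024×1024 sessions), 50 cells, and a 40-trial schedule."""

    frame_height: int = 512
    frame_width: int = 512
    n_frames: int = 2000
    frame_rate: float = 20.0
    pixel_pitch: float = 1.312
    n_cells: int = 50
    soma_radius: float = 5.7  # px; 15 µm diameter at 1.312 µm/px
    background_f0: float = 1000.0  # tissue fluorescence, counts
    cell_f0: float = 300.0  # resting cell fluorescence above tissue, counts
    transient_amplitude: float = 400.0  # counts at soma centre per event
    tau_rise: float = 0.045  # s, GCaMP6f-like
    tau_decay: float = 0.40  # s
    background_rate: float = 0.3  # spontaneous events/s/cell
    p_on: float = 0.9  # P(extra event | positive cell, correct trial)
    suppression_factor: float = 0.1  # rate multiplier for negative cells
    suppression_duration_s: float = 2.0  # post-tone
    frac_positive: float = 0.2
    frac_negative: float = 0.25
    illum_amplitude: float = 0.2  # fractional corner-to-centre vignette
    resp_freq: float = 2.5  # Hz
    resp_amplitude: float = 0.8  # px
    jump_rate: float = 0.01  # events/s
    jump_amplitude: float = 5.0  # px
    bleach_end_fraction: float = 0.933  # intensity remaining at last frame
    read_noise_sigma: float = 15.0  # counts
    shot_noise: bool = True
    quantize: bool = True
    n_trials: int = 40
    iti_range_s: tuple[float, float] = (31.0, 36.0)
    n_correct: int = 33
    trial_start_s: float = 10.0
    eyelid_noise_sigma: float = 1.0
    eyelid_deflection_sd: float = 10.0  # deflection amplitude in baseline SDs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_rate", "pixel_pitch", "soma_radius", "tau_rise", "tau_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_rate", "jump_rate", "resp_freq", "resp_amplitude",
                     "read_noise_sigma", "illum_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.bleach_end_fraction <= 1):
            raise ValueError("bleach_end_fraction must be in (0, 1]")
        if self.n_cells < 0 or self.n_frames < 1:
            raise ValueError("n_cells must be >= 0 and n_frames >= 1")
        if self.n_cells * (2 * self.soma_radius) ** 2 >= self.frame_height * self.frame_width:
            raise ValueError("cell density too high for non-overlapping placement")
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValueError("n_correct must be within [0, n_trials]")
        if self.frac_positive + self.frac_negative > 1:
            raise ValueError("label fractions must sum to <= 1")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class GroundTruth:
    """Simulator record of everything that was planted."""

    cell_centers: np.ndarray  # (n, 2) float (row, col) px
    cell_labels: np.ndarray  # (H, W) int label image, 0 = background
    event_times: list[np.ndarray]  # per cell, seconds
    modulation_label: np.ndarray  # per cell: positive | negative | none
    motion_trace: np.ndarray  # (T, 2) (dx, dy) px
    trial_schedule: TrialTable
    trial_outcomes: np.ndarray  # per trial: correct | incorrect
    session_duration_s: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["placement", "events", "motion", "noise", "schedule", "labels",
             "outcomes", "eyelid"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def transient_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Calcium-transient impulse response: (1 − e^(−t/τr))·e^(−t/τd) for
    t ≥ 0, zero before the event."""
    t = np.asarray(t, dtype=np.float64)
    k = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    return np.where(t >= 0, k, 0.0)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of the transient kernel."""
    return tau_rise * np.log(1.0 + tau_decay / tau_rise)


def _place_cells(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centres with pairwise separation >= 2·r + 2 px
    (so painted somata stay disjoint) and a one-radius border margin."""
    n = params.n_cells
    if n == 0:
        return np.empty((0, 2))
    margin = params.soma_radius + 1.0
    min_sep = 2.0 * params.soma_radius + 2.0
    centers: list[np.ndarray] = []
    max_tries = 1000 * n
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"cell placement infeasible: placed {len(centers)}/{n} "
                f"after {max_tries} tries"
            )
        tries += 1
        cand = np.array(
            [
                rng.uniform(margin, params.frame_height - margin),
                rng.uniform(margin, params.frame_width - margin),
            ]
        )
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    return np.asarray(centers)


def _label_image(params: SimParams, centers: np.ndarray) -> np.ndarray:
    labels = np.zeros((params.frame_height, params.frame_width), dtype=np.uint16)
    r = params.soma_radius
    for k, (cy, cx) in enumerate(centers, start=1):
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[y0:y1, x0:x1][inside] = k
    return labels


def _draw_events(
    params: SimParams,
    schedule: TrialTable,
    outcomes: np.ndarray,
    labels: np.ndarray,
    duration: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Homogeneous background point process per cell, thinned post-tone for
    negative cells, plus an extra tone-locked event for positive cells on
    correct trials."""
    tone = schedule.tone_onset_s
    correct = outcomes == "correct"
    events: list[np.ndarray] = []
    for c in range(params.n_cells):
        n_bg = rng.poisson(params.background_rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n_bg))
        if labels[c] == "negative" and len(times):
            suppressed = np.zeros(len(times), dtype=bool)
            for t0 in tone:
                suppressed |= (times >= t0) & (times < t0 + params.suppression_duration_s)
            keep = ~suppressed | (rng.uniform(size=len(times)) < params.suppression_factor)
            times = times[keep]
        if labels[c] == "positive":
            extra = [
                t0 + rng.uniform(0.0, CS_US_INTERVAL_S)
                for t0, ok in zip(tone, correct)
                if ok and rng.uniform() < params.p_on
            ]
            if extra:
                times = np.sort(np.concatenate([times, extra]))
        events.append(times)
    return events


def make_ground_truth(params: SimParams) -> GroundTruth:
    """Plant cells, events, motion, trial schedule, and modulation labels.

    Deterministic given ``params.seed``.  The session spans at least the
    movie duration and the full trial schedule (plus a post-trial tail), so
    trace-level analyses can use all trials even when the rendered movie is
    shorter.
    """
    rngs = _streams(params.seed)
    schedule = generate_trial_schedule(
        params.n_trials, params.iti_range_s, rngs["schedule"], params.trial_start_s
    )
    outcome_idx = rngs["outcomes"].permutation(params.n_trials)[: params.n_correct]
    outcomes = np.array(["incorrect"] * params.n_trials, dtype=object)
    outcomes[np.sort(outcome_idx)] = "correct"

    n = params.n_cells
    n_pos = int(round(params.frac_positive * n))
    n_neg = int(round(params.frac_negative * n))
    labels = np.array(["none"] * n, dtype=object)
    order = rngs["labels"].permutation(n)
    labels[order[:n_pos]] = "positive"
    labels[order[n_pos : n_pos + n_neg]] = "negative"

    centers = _place_cells(params, rngs["placement"])
    label_img = _label_image(params, centers)

    duration = max(params.duration_s, schedule.tone_onset_s[-1] + 12.0 if params.n_trials else 0.0)
    events = _draw_events(params, schedule, outcomes, labels, duration, rngs["events"])

    t = np.arange(params.n_frames) / params.frame_rate
    phase = rngs["motion"].uniform(0, 2 * np.pi, size=2)
    motion = np.column_stack(
        [
            params.resp_amplitude * np.sin(2 * np.pi * params.resp_freq * t + phase[0]),
            params.resp_amplitude * np.sin(2 * np.pi * params.resp_freq * t + phase[1]),
        ]
    )
    n_jumps = rngs["motion"].poisson(params.jump_rate * params.duration_s)
    jump_frames = rngs["motion"].integers(1, max(params.n_frames - 1, 2), size=n_jumps)
    for jf in jump_frames:
        direction = rngs["motion"].uniform(0, 2 * np.pi)
        vec = params.jump_amplitude * np.array([np.cos(direction), np.sin(direction)])
        motion[jf] += vec  # biphasic two-frame excursion
        if jf + 1 < params.n_frames:
            motion[jf + 1] -= 0.5 * vec

    return GroundTruth(
        cell_centers=centers,
        cell_labels=label_img,
        event_times=events,
        modulation_label=labels,
        motion_trace=motion,
        trial_schedule=schedule,
        trial_outcomes=outcomes,
        session_duration_s=duration,
    )


def illumination_field(params: SimParams) -> np.ndarray:
    """Static multiplicative vignette: 1 at a slightly off-centre optical
    axis falling quadratically to 1 − illum_amplitude at the far corner."""
    h, w = params.frame_height, params.frame_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = 0.45 * h, 0.55 * w
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return 1.0 - params.illum_amplitude * d2 / d2.max()


def bleach_profile(params: SimParams) -> np.ndarray:
    """Exponential decay from 1 to bleach_end_fraction over the movie."""
    if params.n_frames == 1:
        return np.ones(1)
    exponent = np.arange(params.n_frames) / (params.n_frames - 1)
    return params.bleach_end_fraction**exponent


def _soma_profile(params: SimParams, cy: float, cx: float):
    """Soft-edged soma footprint and its patch slices."""
    r = params.soma_radius
    pad = int(np.ceil(2.2 * r))
    y0 = max(int(np.floor(cy)) - pad, 0)
    x0 = max(int(np.floor(cx)) - pad, 0)
    y1 = min(int(np.ceil(cy)) + pad + 1, params.frame_height)
    x1 = min(int(np.ceil(cx)) + pad + 1, params.frame_width)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    rho = np.hypot(yy - cy, xx - cx) / r
    profile = 1.0 / (1.0 + rho**6)  # ~1 inside the soma, fast roll-off
    return (slice(y0, y1), slice(x0, x1)), profile


def _activity_matrix(
    params: SimParams, events: list[np.ndarray], t: np.ndarray
) -> np.ndarray:
    """Per-cell transient activity summed over events, on the frame grid."""
    n = len(events)
    act = np.zeros((n, len(t)), dtype=np.float64)
    span = int(np.ceil((params.tau_rise + 8 * params.tau_decay) * params.frame_rate)) + 1
    for c, times in enumerate(events):
        for te in times:
            i0 = int(np.ceil((te - 1e-9) * params.frame_rate))
            if i0 >= len(t):
                continue
            i0 = max(i0, 0)
            i1 = min(i0 + span, len(t))
            act[c, i0:i1] += transient_kernel(t[i0:i1] - te, params.tau_rise, params.tau_decay)
    return act


def render_movie(gt: GroundTruth, params: SimParams) -> VideoSequence:
    """Render the movie described by a ground-truth record.

    Per frame: the static scene (tissue background + resting somata) plus
    amplitude-scaled transients is shifted by the planted motion, multiplied
    by the illumination vignette and the bleaching envelope, corrupted by
    shot and read noise, and quantized to 16-bit counts.
    """
    h, w = params.frame_height, params.frame_width
    t = np.arange(params.n_frames) / params.frame_rate
    base = np.full((h, w), params.background_f0, dtype=np.float64)
    patches = []
    for cy, cx in gt.cell_centers:
        sl, profile = _soma_profile(params, cy, cx)
        patches.append((sl, profile))
        base[sl] += params.cell_f0 * profile
    act = _activity_matrix(params, gt.event_times, t)
    illum = illumination_field(params)
    bleach = bleach_profile(params)
    rng = _streams(params.seed)["noise"]

    out = np.empty(
        (params.n_frames, h, w), dtype=np.uint16 if params.quantize else np.float32
    )
    for i in range(params.n_frames):
        frame = base.copy()
        active = np.nonzero(act[:, i] > 1e-12)[0]
        for c in active:
            sl, profile = patches[c]
            frame[sl] += params.transient_amplitude * act[c, i] * profile
        dx, dy = gt.motion_trace[i]
        if dx != 0 or dy != 0:
            frame = apply_shift(frame, dx, dy)
        frame *= illum * bleach[i]
        if params.shot_noise:
            frame = frame + rng.standard_normal((h, w)) * np.sqrt(np.maximum(frame, 0.0))
        if params.read_noise_sigma > 0:
            frame = frame + rng.standard_normal((h, w)) * params.read_noise_sigma
        if params.quantize:
            out[i] = np.clip(np.floor(frame + 0.5), 0, 65535).astype(np.uint16)
        else:
            out[i] = frame
    return VideoSequence(out, params.frame_rate, params.pixel_pitch, t0=0.0)


def render_traces(gt: GroundTruth, params: SimParams) -> TraceMatrix:
    """Render per-cell raw traces over the whole session without imaging.

    The trace-level model matches what mean-over-mask extraction would see
    in a motionless, vignette-free movie: resting fluorescence plus scaled
    transients, with Gaussian noise reduced by mask-pixel averaging.  Used
    to validate trial-aligned statistics at full 40-trial session length
    without rendering a half-hour movie.
    """
    n_samples = int(np.ceil(gt.session_duration_s * params.frame_rate))
    t = np.arange(n_samples) / params.frame_rate
    act = _activity_matrix(params, gt.event_times, t)
    f0 = params.background_f0 + params.cell_f0
    mask_area = max(np.pi * params.soma_radius**2, 1.0)
    sigma = np.sqrt(params.read_noise_sigma**2 + f0) / np.sqrt(mask_area)
    rng = _streams(params.seed)["noise"]
    raw = f0 + params.transient_amplitude * act
    raw = raw + rng.standard_normal(raw.shape) * sigma
    return TraceMatrix(
        raw=raw,
        times=t,
        roi_ids=np.arange(1, gt.n_cells + 1),
        frame_rate=params.frame_rate,
    )


def render_eyelid(gt: GroundTruth, params: SimParams) -> EyelidTrace:
    """Render the eyelid-reflection trace implied by the planted outcomes.

    Gaussian baseline noise throughout; on planted-correct trials an
    anticipatory deflection (default 10× the baseline SD) starts within the
    600 ms post-tone window and peaks before the puff; every trial also gets
    a reflexive post-puff blink.  Incorrect trials show no pre-puff
    deflection.
    """
    fs = params.frame_rate
    n_samples = int(np.ceil(gt.session_duration_s * fs))
    rng = _streams(params.seed)["eyelid"]
    sigma = params.eyelid_noise_sigma
    trace = rng.standard_normal(n_samples) * sigma
    amp = params.eyelid_deflection_sd * sigma
    t_axis = np.arange(n_samples) / fs

    def add_blink(onset: float, duration: float = 0.4) -> None:
        sel = (t_axis >= onset) & (t_axis < onset + duration)
        trace[sel] += amp * np.sin(np.pi * (t_axis[sel] - onset) / duration) ** 2

    for tone, outcome in zip(gt.trial_schedule.tone_onset_s, gt.trial_outcomes):
        puff = tone + CS_US_INTERVAL_S
        if outcome == "correct" and amp > 0:
            onset = tone + rng.uniform(0.05, 0.30)
            add_blink(onset, duration=0.4)
        add_blink(puff + 0.05, duration=0.3)  # reflexive blink, both outcomes
    return EyelidTrace(reflection=trace, frame_rate=fs, t0=0.0)


def simulate_session(params: SimParams) -> tuple[GroundTruth, VideoSequence, EyelidTrace]:
    """Convenience wrapper: ground truth, rendered movie, eyelid trace."""
    gt = make_ground_truth(params)
    movie = render_movie(gt, params)
    eyelid = render_eyelid(gt, params)
    return gt, movie, eyelid
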