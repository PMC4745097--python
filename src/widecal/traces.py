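"""Per-ROI fluorescence traces, Δf normalization, SNR, and photobleaching.

Traces are extracted from the motion-corrected native-depth movie (the 8-bit
reduced copy is for storage/visualization only).  Normalization follows the
Δf = (f − f_avg)/f_avg convention with the whole-session mean as f_avg, then
a single positive rescale per trace so its maximum equals 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .merge import MultiFrameROI
from .video import VideoSequence


@dataclass
class TraceMatrix:
    raw: np.ndarray  # (R, T) counts
    times: np.ndarray  # (T,) seconds
    roi_ids: np.ndarray  # (R,)
    frame_rate: float
    dff: np.ndarray | None = None  # (R, T) percent of per-trace max
    f_avg: np.ndarray | None = None  # (R,)

    @property
    def n_rois(self) -> int:
        return self.raw.shape[0]

    def to_dataframe(self):
        import pandas as pd

        R, T = self.raw.shape
        dff = self.dff if self.dff is not None else np.full_like(self.raw, np.nan)
        return pd.DataFrame(
            {
                "roi_id": np.repeat(self.roi_ids, T),
                "frame": np.tile(np.arange(T), R),
                "time_s": np.tile(self.times, R),
                "raw": self.raw.ravel(),
                "dff": dff.ravel(),
            }
        )


@dataclass
class ROIQuality:
    snr: np.ndarray  # per ROI
    noise_sigma: float  # shared noise level, counts
    bleach_percent: float | None = None


def extract_traces(video: VideoSequence, rois: Sequence[MultiFrameROI]) -> TraceMatrix:
    """Mean-over-mask fluorescence of every ROI in every frame."""
    frames = video.frames
    R = len(rois)
    T = frames.shape[0]
    raw = np.empty((R, T), dtype=np.float64)
    for i, roi in enumerate(rois):
        if roi.area == 0:
            raise ValueError(f"ROI {roi.id} has an empty mask")
        rr, cc = roi.mask[:, 0], roi.mask[:, 1]
        if rr.max() >= frames.shape[1] or cc.max() >= frames.shape[2]:
            raise ValueError(f"ROI {roi.id} mask outside frame bounds")
        raw[i] = frames[:, rr, cc].mean(axis=1)
    return TraceMatrix(
        raw=raw,
        times=video.times,
        roi_ids=np.asarray([r.id for r in rois], dtype=np.int64),
        frame_rate=video.frame_rate,
    )


def normalize_trace(raw: np.ndarray) -> np.ndarray:
    """Δf normalization rescaled so the trace maximum is exactly 100%.

    d = (f − f_avg)/f_avg; if max(d) > 0 the whole trace (negative excursions
    included) is multiplied by 100/max(d), otherwise the output is all zero.
    """
    raw = np.asarray(raw, dtype=np.float64)
    f_avg = raw.mean()
    if f_avg == 0:
        raise ValueError("trace mean is zero; Δf undefined")
    d = (raw - f_avg) / f_avg
    m = d.max()
    if m > 0:
        return d * (100.0 / m)
    return np.zeros_like(d)


def normalize_traces(tm: TraceMatrix) -> TraceMatrix:
    """Fill the dff and f_avg fields of a trace matrix (returns it)."""
    tm.f_avg = tm.raw.mean(axis=1)
    tm.dff = np.vstack([normalize_trace(row) for row in tm.raw]) if tm.n_rois else np.empty_like(tm.raw)
    return tm


def compute_snr(
    video: VideoSequence,
    rois: Sequence[MultiFrameROI],
    traces: TraceMatrix,
    chunk_frames: int = 200,
) -> ROIQuality:
    """Max-over-noise SNR per ROI.

    The shared noise level is the mean, over all pixels not registered to
    any ROI, of each pixel's temporal standard deviation; each ROI's maximum
    raw trace intensity is divided by that value.
    """
    H, W = video.frame_shape
    in_roi = np.zeros((H, W), dtype=bool)
    for roi in rois:
        in_roi[roi.mask[:, 0], roi.mask[:, 1]] = True
    if in_roi.all():
        raise ValueError("no non-ROI pixels available for noise estimation")
    outside = ~in_roi
    T = video.n_frames
    s1 = np.zeros(np.count_nonzero(outside), dtype=np.float64)
    s2 = np.zeros_like(s1)
    for lo in range(0, T, chunk_frames):
        chunk = np.asarray(video.frames[lo : lo + chunk_frames], dtype=np.float64)[:, outside]
        s1 += chunk.sum(axis=0)
        s2 += np.square(chunk).sum(axis=0)
    mean = s1 / T
    var = np.maximum(s2 / T - mean**2, 0.0)
    noise_sigma = float(np.sqrt(var).mean())
    if noise_sigma == 0:
        raise ValueError("zero noise estimate; SNR undefined")
    snr = traces.raw.max(axis=1) / noise_sigma
    return ROIQuality(snr=snr, noise_sigma=noise_sigma)


def photobleaching_percent(video: VideoSequence, end_frames: int = 1) -> float:
    """Whole-field mean intensity loss from the first to the last frame, %.

    Optionally averages ``end_frames`` frames at each end to suppress noise.
    A brightening movie yields a negative percentage, reported as-is.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    k = max(1, int(end_frames))
    first = float(np.asarray(video.frames[:k], dtype=np.float64).mean())
    last = float(np.asarray(video.frames[-k:], dtype=np.float64).mean())
    if first == 0:
        raise ValueError("first-frame mean is zero")
    return 100.0 * (first - last) / first
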