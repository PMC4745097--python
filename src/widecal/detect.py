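"""Activity-based ROI detection.

Each motion-corrected frame is reduced to a binary activity map by
thresholding the per-pixel z-score of intensity: a pixel overlying a cell
that fires in that frame sits several temporal standard deviations above its
own mean.  The threshold adapts per frame so that global brightness swings or
residual motion never flood the frame with "active" pixels.  Cleaned binary
maps are labeled into connected components ("single-frame ROIs"), size-gated
by soma morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .video import FrameStats, VideoSequence


@dataclass
class DetectionParams:
    z0: float = 1.5
    z_bounds: tuple[float, float] = (1.0, 6.0)
    z_step: float = 0.25
    active_frac_bounds: tuple[float, float] = (0.0005, 0.01)
    open_radius: int = 1
    close_radius: int = 1
    connectivity: int = 8
    area_bounds: tuple[int, int] = (30, 300)
    max_iters: int = 20

    def __post_init__(self) -> None:
        z_min, z_max = self.z_bounds
        if not (z_min <= self.z0 <= z_max):
            raise ValueError("z0 must lie within z_bounds")
        lo, hi = self.active_frac_bounds
        if not (0 <= lo < hi <= 1):
            raise ValueError("active_frac_bounds must satisfy 0 <= lo < hi <= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.area_bounds[0] >= self.area_bounds[1]:
            raise ValueError("area_bounds must satisfy min < max")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")


@dataclass
class SingleFrameROI:
    """A connected active component in one frame."""

    frame_index: int
    pixels: np.ndarray  # (N, 2) array of (row, col)
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    mean_intensity: float
    max_intensity: float

    @property
    def area(self) -> int:
        return len(self.pixels)


def zscore_frame(frame: np.ndarray, stats: FrameStats) -> np.ndarray:
    """Per-pixel z-score of a frame against its temporal statistics.

    Pixels with zero temporal std get z = 0 rather than ±inf.
    """
    frame = np.asarray(frame, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (frame - stats.mean) / stats.std
    return np.where(stats.std > 0, z, 0.0)


def adaptive_threshold(
    zmap: np.ndarray, params: DetectionParams | None = None
) -> tuple[np.ndarray, float]:
    """Threshold a z-map, adapting the cut so the active fraction is sane.

    Starting from ``z0``, the threshold is raised by ``z_step`` while the
    fraction of supra-threshold pixels exceeds the upper bound (which guards
    against motion-induced high-contrast borders lighting up whole frames)
    and lowered while it falls below the lower bound, clamped to ``z_bounds``
    and capped at ``max_iters`` adjustments.

    Returns (mask, final_threshold).
    """
    params = params or DetectionParams()
    zmap = np.asarray(zmap, dtype=np.float64)
    if not np.all(np.isfinite(zmap)):
        raise ValueError("z-map contains non-finite values")
    z_min, z_max = params.z_bounds
    lo, hi = params.active_frac_bounds
    n = zmap.size
    z = float(params.z0)
    raised = False
    for _ in range(params.max_iters):
        frac = np.count_nonzero(zmap > z) / n
        if frac > hi and z < z_max:
            z = min(z + params.z_step, z_max)
            raised = True
        elif frac < lo and z > z_min and not raised:
            # lowering after a raise would oscillate; prefer the sparse side
            z = max(z - params.z_step, z_min)
        else:
            break
    return zmap > z, z


def _clean_structure(radius: int) -> np.ndarray:
    # radius 1 uses the full 3x3 square (Chebyshev ball) so compact convex
    # shapes survive opening unchanged; larger radii use a Euclidean disk
    if radius <= 1:
        return np.ones((3, 3), dtype=bool)
    return disk(radius)


def clean_binary(mask: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Morphological closing then opening of the activity mask."""
    params = params or DetectionParams()
    mask = np.asarray(mask, dtype=bool)
    if params.close_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_clean_structure(params.close_radius))
    if params.open_radius > 0:
        mask = ndimage.binary_opening(mask, structure=_clean_structure(params.open_radius))
    return mask


def _label_structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    return ndimage.generate_binary_structure(2, 1)


def label_components(
    mask: np.ndarray,
    frame: np.ndarray,
    params: DetectionParams | None = None,
    frame_index: int = 0,
) -> list[SingleFrameROI]:
    """Label connected components of a cleaned mask into single-frame ROIs.

    Components with area outside ``area_bounds`` are discarded (CA1 soma
    morphology: a 15 µm cell at 1.312 µm/px covers ~103 px).  Centroids are
    unweighted pixel means; bounding boxes are half-open.
    """
    params = params or DetectionParams()
    frame = np.asarray(frame)
    labels, n = ndimage.label(mask, structure=_label_structure(params.connectivity))
    rois: list[SingleFrameROI] = []
    if n == 0:
        return rois
    a_min, a_max = params.area_bounds
    slices = ndimage.find_objects(labels)
    for k, sl in enumerate(slices, start=1):
        local = labels[sl] == k
        area = int(local.sum())
        if not (a_min <= area <= a_max):
            continue
        rr, cc = np.nonzero(local)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        vals = frame[rr, cc].astype(np.float64)
        rois.append(
            SingleFrameROI(
                frame_index=frame_index,
                pixels=np.column_stack([rr, cc]).astype(np.int32),
                centroid=(float(rr.mean()), float(cc.mean())),
                bbox=(int(rr.min()), int(rr.max()) + 1, int(cc.min()), int(cc.max()) + 1),
                mean_intensity=float(vals.mean()),
                max_intensity=float(vals.max()),
            )
        )
    return rois


def detect_rois(
    video: VideoSequence,
    stats: FrameStats,
    params: DetectionParams | None = None,
) -> list[list[SingleFrameROI]]:
    """Run zscore → adaptive threshold → clean → label on every frame.

    Cost is linear in frames and pixels.  Returns one (possibly empty) list
    of single-frame ROIs per frame.
    """
    params = params or DetectionParams()
    out: list[list[SingleFrameROI]] = []
    for t in range(video.n_frames):
        frame = video.frames[t]
        zmap = zscore_frame(frame, stats)
        mask, _ = adaptive_threshold(zmap, params)
        mask = clean_binary(mask, params)
        out.append(label_components(mask, frame, params, frame_index=t))
    return out
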