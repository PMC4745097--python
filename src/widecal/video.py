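"""Movie container, TIFF I/O, per-pixel statistics, and bit-depth reduction.

A recording session is a stack of grayscale frames acquired at a fixed frame
rate with a known pixel pitch (µm per pixel).  Everything downstream operates
on the :class:`VideoSequence` container defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile


@dataclass
class VideoSequence:
    """A T×H×W intensity movie with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Pixel intensities, 8/16-bit counts or float.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_pitch : float
        Size of one pixel in µm (isotropic).
    t0 : float
        Time of the first frame in seconds.
    """

    frames: np.ndarray
    frame_rate: float = 20.0
    pixel_pitch: float = 1.312
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def with_frames(self, frames: np.ndarray) -> "VideoSequence":
        return VideoSequence(frames, self.frame_rate, self.pixel_pitch, self.t0)


@dataclass
class FrameStats:
    """Per-pixel temporal statistics (H×W maps) of a movie."""

    min: np.ndarray
    max: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.min, self.max, self.mean, self.std)}
        if len(shapes) != 1:
            raise ValueError("all statistic maps must share one shape")


def read_tiff_sequence(
    paths: Sequence[str | Path] | str | Path,
    frame_rate: float = 20.0,
    pixel_pitch: float = 1.312,
    t0: float = 0.0,
) -> VideoSequence:
    """Read one or more multi-page TIFF files into a single movie.

    Pages are concatenated in path order then page order.  All pages must
    share dimensions and bit depth; acquisition metadata comes from the
    arguments (TIFF tags are not trusted).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no input files given")
    stacks = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(str(p))
        arr = tifffile.imread(str(p))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{p}: expected grayscale pages, got shape {arr.shape}")
        stacks.append(arr)
    shapes = {s.shape[1:] for s in stacks}
    dtypes = {s.dtype for s in stacks}
    if len(shapes) > 1:
        raise ValueError(f"mixed page dimensions across files: {sorted(shapes)}")
    if len(dtypes) > 1:
        raise ValueError(f"mixed bit depths across files: {sorted(map(str, dtypes))}")
    frames = np.concatenate(stacks, axis=0)
    if frames.shape[0] == 0:
        raise ValueError("zero pages read")
    return VideoSequence(frames, frame_rate, pixel_pitch, t0)


def write_tiff(video: VideoSequence | np.ndarray, path: str | Path) -> None:
    """Write a movie as a little-endian multi-page grayscale TIFF."""
    frames = video.frames if isinstance(video, VideoSequence) else np.asarray(video)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def compute_pixel_stats(video: VideoSequence, chunk_frames: int | None = None) -> FrameStats:
    """Exact per-pixel min/max/mean/std over time.

    Uses the population (1/T) standard-deviation convention.  When
    ``chunk_frames`` is given, frames are visited in chunks of that size with
    float64 accumulators; chunk boundaries do not change the result.
    """
    frames = video.frames
    T = frames.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames for a temporal std")
    if chunk_frames is None:
        chunk_frames = min(T, 256)
    shape = frames.shape[1:]
    mn = np.full(shape, np.inf)
    mx = np.full(shape, -np.inf)
    s1 = np.zeros(shape, dtype=np.float64)
    s2 = np.zeros(shape, dtype=np.float64)
    for lo in range(0, T, chunk_frames):
        chunk = np.asarray(frames[lo : lo + chunk_frames], dtype=np.float64)
        np.minimum(mn, chunk.min(axis=0), out=mn)
        np.maximum(mx, chunk.max(axis=0), out=mx)
        s1 += chunk.sum(axis=0)
        s2 += np.square(chunk).sum(axis=0)
    mean = s1 / T
    var = np.maximum(s2 / T - mean**2, 0.0)
    return FrameStats(min=mn, max=mx, mean=mean, std=np.sqrt(var))


def _pooled_percentiles(frames: np.ndarray, qs: Sequence[float]) -> np.ndarray:
    """Linear-interpolation percentiles over the pooled pixel×time values.

    Integer movies use an exact counting-sort path so that arbitrarily long
    sessions need no full sort; the result is identical to ``np.percentile``.
    """
    if np.issubdtype(frames.dtype, np.integer) and frames.dtype.itemsize <= 2:
        offset = 0
        data = frames
        if np.issubdtype(frames.dtype, np.signedinteger):  # pragma: no cover
            data = frames.astype(np.int64) - int(frames.min())
            offset = int(frames.min())
        counts = np.bincount(data.ravel(), minlength=1)
        cum = np.cumsum(counts)
        n = cum[-1]
        out = []
        for q in qs:
            pos = q / 100.0 * (n - 1)
            i = int(np.floor(pos))
            frac = pos - i
            v_lo = int(np.searchsorted(cum, i + 1))
            v_hi = v_lo if frac == 0 else int(np.searchsorted(cum, i + 2))
            out.append(v_lo + frac * (v_hi - v_lo) + offset)
        return np.asarray(out, dtype=np.float64)
    return np.percentile(frames, qs)


def reduce_bit_depth(
    video: VideoSequence,
    stats: FrameStats | None = None,
    lo_percent: float = 1.0,
    hi_percent: float = 99.0,
) -> VideoSequence:
    """Reduce a movie to 8-bit dynamic range.

    The global 1st/99th percentiles of all pixel values define the clip
    points: the top 1% of intensities saturate at 255 and the bottom 1% map
    to 0, with a linear map in between (rounded half-up).
    """
    p_lo, p_hi = _pooled_percentiles(video.frames, [lo_percent, hi_percent])
    if p_hi <= p_lo:
        warnings.warn("degenerate intensity range; emitting an all-zero 8-bit movie")
        return video.with_frames(np.zeros(video.frames.shape, dtype=np.uint8))
    scaled = (np.asarray(video.frames, dtype=np.float64) - p_lo) * (255.0 / (p_hi - p_lo))
    out = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return video.with_frames(out)


def field_of_view(video: VideoSequence) -> tuple[float, float]:
    """Imaging field of view as (width_mm, height_mm), rounded to 3 decimals."""
    h, w = video.frame_shape
    return (
        round(w * video.pixel_pitch / 1000.0, 3),
        round(h * video.pixel_pitch / 1000.0, 3),
    )
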