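"""Cluster single-frame ROIs into multi-frame neuron ROIs.

A cell that fires in many frames leaves a stack of near-coincident
single-frame ROIs.  Clustering joins them by proximity of centroids and of
bounding-box corners, with a coarse area-bucket prefilter ("grouping by
size").  For large frames the work is pre-grouped into overlapping spatial
blocks, and a second redundancy pass merges clusters rediscovered in
adjacent blocks; blocked and unblocked clustering give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import SingleFrameROI


@dataclass
class MergeParams:
    centroid_tol: float = 8.0
    bbox_tol: float = 12.0
    block_size: int = 128
    block_overlap: int = 32
    min_frames: int = 5
    mask_freq_threshold: float = 0.25
    max_iou: float = 0.3
    size_bucket_slack: int = 1  # allow +-N doubling buckets in the area prefilter

    def __post_init__(self) -> None:
        if self.centroid_tol > self.bbox_tol:
            raise ValueError("centroid_tol must be <= bbox_tol")
        if not (0 <= self.block_overlap < self.block_size):
            raise ValueError("block_overlap must satisfy 0 <= overlap < block_size")
        if not (0 < self.mask_freq_threshold <= 1):
            raise ValueError("mask_freq_threshold must be in (0, 1]")
        if not (0 < self.max_iou < 1):
            raise ValueError("max_iou must be in (0, 1)")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")


@dataclass
class MultiFrameROI:
    """A putative neuron: merged footprint and the frames it appeared in."""

    id: int
    mask: np.ndarray  # (N, 2) pixel array (row, col)
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    frame_indices: np.ndarray
    n_appearances: int

    @property
    def area(self) -> int:
        return len(self.mask)

    def centroid_um(self, pixel_pitch: float) -> tuple[float, float]:
        return (self.centroid[0] * pixel_pitch, self.centroid[1] * pixel_pitch)

    def mask_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.mask}


def _corners(bbox: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    r0, r1, c0, c1 = bbox
    return np.array([r0, c0], dtype=float), np.array([r1, c1], dtype=float)


def roi_similar(a, b, params: MergeParams | None = None) -> bool:
    """True iff centroids and both bounding-box corners are proximal.

    ``a`` and ``b`` may be single-frame ROIs, clusters, or anything exposing
    ``centroid`` and ``bbox``; the test is the conjunction of a Euclidean
    centroid-distance gate and Euclidean gates on the upper-left and
    lower-right bbox corners.
    """
    params = params or MergeParams()
    ca = np.asarray(a.centroid, dtype=float)
    cb = np.asarray(b.centroid, dtype=float)
    if np.hypot(*(ca - cb)) > params.centroid_tol:
        return False
    a_ul, a_lr = _corners(a.bbox)
    b_ul, b_lr = _corners(b.bbox)
    if np.hypot(*(a_ul - b_ul)) > params.bbox_tol:
        return False
    if np.hypot(*(a_lr - b_lr)) > params.bbox_tol:
        return False
    return True


class _Cluster:
    """Incremental cluster of single-frame ROIs with running summaries."""

    __slots__ = ("member_ids", "members", "_centroid_sum", "_bbox_sum", "order")

    def __init__(self, order: int):
        self.member_ids: list[int] = []
        self.members: list[SingleFrameROI] = []
        self._centroid_sum = np.zeros(2)
        self._bbox_sum = np.zeros(4)
        self.order = order

    def add(self, roi_id: int, roi: SingleFrameROI) -> None:
        self.member_ids.append(roi_id)
        self.members.append(roi)
        self._centroid_sum += roi.centroid
        self._bbox_sum += roi.bbox

    @property
    def centroid(self) -> np.ndarray:
        return self._centroid_sum / len(self.members)

    @property
    def bbox(self) -> np.ndarray:
        return self._bbox_sum / len(self.members)

    @property
    def mean_area(self) -> float:
        return float(np.mean([m.area for m in self.members]))


def _area_bucket(area: float) -> int:
    return int(np.floor(np.log2(max(area, 1))))


def _cluster_incremental(
    indexed_rois: list[tuple[int, SingleFrameROI]], params: MergeParams, order0: int = 0
) -> list[_Cluster]:
    """Single-linkage incremental clustering in frame order.

    Each ROI joins the most centroid-proximal existing similar cluster
    (earliest cluster on exact ties), else seeds a new cluster.  The area
    prefilter only compares ROIs in neighbouring doubling buckets.
    """
    clusters: list[_Cluster] = []
    for roi_id, roi in indexed_rois:
        bucket = _area_bucket(roi.area)
        best = None
        best_dist = np.inf
        for cl in clusters:
            if abs(_area_bucket(cl.mean_area) - bucket) > params.size_bucket_slack:
                continue
            if not roi_similar(roi, cl, params):
                continue
            dist = float(np.hypot(*(np.asarray(roi.centroid) - cl.centroid)))
            if dist < best_dist:
                best, best_dist = cl, dist
        if best is None:
            best = _Cluster(order0 + len(clusters))
            clusters.append(best)
        best.add(roi_id, roi)
    return clusters


def _block_origins(extent: int, block: int, step: int) -> list[int]:
    if extent <= block:
        return [0]
    origins = list(range(0, extent - block + step, step))
    return origins


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _finalize(
    groups: list[list[tuple[int, SingleFrameROI]]], params: MergeParams
) -> list[MultiFrameROI]:
    """Build multi-frame ROIs: frequency-thresholded mask, frame filter."""
    out: list[MultiFrameROI] = []
    for members in groups:
        # dedupe members shared between overlapping blocks
        seen: dict[int, SingleFrameROI] = {}
        for rid, roi in members:
            seen.setdefault(rid, roi)
        rois = [seen[rid] for rid in sorted(seen)]
        frames = sorted({r.frame_index for r in rois})
        if len(frames) < params.min_frames:
            continue
        # pixel presence counted once per contributing frame
        per_frame: dict[int, set[tuple[int, int]]] = {}
        for r in rois:
            s = per_frame.setdefault(r.frame_index, set())
            s.update(map(tuple, r.pixels))
        counts: dict[tuple[int, int], int] = {}
        for s in per_frame.values():
            for px in s:
                counts[px] = counts.get(px, 0) + 1
        need = params.mask_freq_threshold * len(frames) - 1e-9
        mask = sorted(px for px, c in counts.items() if c >= need)
        if not mask:
            continue
        mask_arr = np.asarray(mask, dtype=np.int32)
        centroids = np.asarray([r.centroid for r in rois])
        centroid = tuple(centroids.mean(axis=0))
        r0, c0 = mask_arr.min(axis=0)
        r1, c1 = mask_arr.max(axis=0) + 1
        out.append(
            MultiFrameROI(
                id=-1,
                mask=mask_arr,
                centroid=(float(centroid[0]), float(centroid[1])),
                bbox=(int(r0), int(r1), int(c0), int(c1)),
                frame_indices=np.asarray(frames, dtype=np.int64),
                n_appearances=len(frames),
            )
        )
    # deterministic ids by first (smallest) member pixel-order: sort by centroid
    out.sort(key=lambda m: (m.frame_indices[0], m.centroid))
    for k, m in enumerate(out, start=1):
        m.id = k
    return out


def cluster_rois(
    sfrois: Sequence[Sequence[SingleFrameROI]] | Sequence[SingleFrameROI],
    params: MergeParams | None = None,
    frame_shape: tuple[int, int] | None = None,
    use_blocks: bool = True,
) -> list[MultiFrameROI]:
    """Merge single-frame ROIs into multi-frame ROIs.

    ``sfrois`` is either per-frame lists (from :func:`~widecal.detect.detect_rois`)
    or a flat frame-sorted list.  With ``use_blocks`` the image is tiled into
    overlapping blocks (each ROI is assigned to every block containing its
    centroid), clustering runs per block, and a redundancy pass merges
    clusters across blocks that share members or satisfy
    :func:`roi_similar`.  The final mask keeps pixels present in at least
    ``mask_freq_threshold`` of the contributing frames; clusters appearing in
    fewer than ``min_frames`` distinct frames are dropped.
    """
    params = params or MergeParams()
    if sfrois and isinstance(sfrois[0], SingleFrameROI):
        flat = list(sfrois)
    else:
        flat = [roi for frame_list in sfrois for roi in frame_list]
    flat.sort(key=lambda r: r.frame_index)
    indexed = list(enumerate(flat))
    if not indexed:
        return []

    if not use_blocks:
        clusters = [(0, cl) for cl in _cluster_incremental(indexed, params)]
        return _finalize(_merge_redundant(clusters, flat, params), params)

    if frame_shape is None:
        max_r = max(r.bbox[1] for r in flat)
        max_c = max(r.bbox[3] for r in flat)
        frame_shape = (max_r, max_c)
    step = params.block_size - params.block_overlap
    row_origins = _block_origins(frame_shape[0], params.block_size, step)
    col_origins = _block_origins(frame_shape[1], params.block_size, step)

    all_clusters: list[tuple[int, _Cluster]] = []  # (block index, cluster)
    bidx = 0
    for r0 in row_origins:
        for c0 in col_origins:
            r1 = r0 + params.block_size if r0 + params.block_size < frame_shape[0] else np.inf
            c1 = c0 + params.block_size if c0 + params.block_size < frame_shape[1] else np.inf
            members = [
                (rid, roi)
                for rid, roi in indexed
                if r0 <= roi.centroid[0] < r1 and c0 <= roi.centroid[1] < c1
            ]
            for cl in _cluster_incremental(members, params, order0=len(all_clusters)):
                all_clusters.append((bidx, cl))
            bidx += 1

    return _finalize(_merge_redundant(all_clusters, flat, params), params)


def _merge_redundant(
    clusters: list[tuple[int, _Cluster]],
    flat: list[SingleFrameROI],
    params: MergeParams,
) -> list[list[tuple[int, SingleFrameROI]]]:
    """Redundancy pass: single-linkage merge of clusters that share members
    (rediscovered in overlapping blocks) or whose summaries are similar
    (the same cell split by detection jitter)."""
    uf = _UnionFind(len(clusters))
    member_map: dict[int, list[int]] = {}
    for ci, (_, cl) in enumerate(clusters):
        for rid in cl.member_ids:
            member_map.setdefault(rid, []).append(ci)
    for owners in member_map.values():
        for other in owners[1:]:
            uf.union(owners[0], other)
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if uf.find(i) == uf.find(j):
                continue
            if roi_similar(clusters[i][1], clusters[j][1], params):
                uf.union(i, j)

    groups: dict[int, list[tuple[int, SingleFrameROI]]] = {}
    for ci, (_, cl) in enumerate(clusters):
        root = uf.find(ci)
        groups.setdefault(root, []).extend((rid, flat[rid]) for rid in cl.member_ids)
    return [groups[k] for k in sorted(groups)]


def _iou(a: MultiFrameROI, b: MultiFrameROI) -> float:
    sa, sb = a.mask_set(), b.mask_set()
    inter = len(sa & sb)
    if inter == 0:
        return 0.0
    return inter / len(sa | sb)


def filter_separated(
    rois: Sequence[MultiFrameROI], params: MergeParams | None = None
) -> list[MultiFrameROI]:
    """Drop spatially redundant ROIs until no pair overlaps above max_iou.

    Greedy on the worst-offending pair: the member with fewer appearances is
    dropped (ties: smaller area, then larger id).  This is the algorithmic
    surrogate for manual curation of overlapping detections.
    """
    params = params or MergeParams()
    survivors = list(rois)
    while True:
        worst = None
        worst_iou = params.max_iou
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                v = _iou(survivors[i], survivors[j])
                if v > worst_iou or (
                    worst is not None
                    and v == worst_iou
                    and (survivors[i].id, survivors[j].id) < worst_key
                ):
                    worst = (i, j)
                    worst_key = (survivors[i].id, survivors[j].id)
                    worst_iou = v
        if worst is None:
            break
        a, b = survivors[worst[0]], survivors[worst[1]]
        loser = _pick_loser(a, b)
        survivors.remove(loser)
    return survivors


def _pick_loser(a: MultiFrameROI, b: MultiFrameROI) -> MultiFrameROI:
    if a.n_appearances != b.n_appearances:
        return a if a.n_appearances < b.n_appearances else b
    if a.area != b.area:
        return a if a.area < b.area else b
    return a if a.id > b.id else b
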