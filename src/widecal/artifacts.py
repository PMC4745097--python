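"""Serialization of intermediate artifacts: ROI JSON + label TIFF,
single-frame ROI JSON lines, ground-truth JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .detect import SingleFrameROI
from .merge import MultiFrameROI
from .synth import GroundTruth


def save_sfrois(sfrois: Sequence[Sequence[SingleFrameROI]], path: str | Path) -> None:
    """One JSON object per single-frame ROI (JSON lines)."""
    with open(path, "w") as fh:
        for frame_list in sfrois:
            for roi in frame_list:
                fh.write(
                    json.dumps(
                        {
                            "frame_index": roi.frame_index,
                            "pixels": roi.pixels.tolist(),
                            "centroid": list(roi.centroid),
                            "bbox": list(roi.bbox),
                            "mean_intensity": roi.mean_intensity,
                            "max_intensity": roi.max_intensity,
                        }
                    )
                    + "\n"
                )


def load_sfrois(path: str | Path) -> list[SingleFrameROI]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(
                SingleFrameROI(
                    frame_index=d["frame_index"],
                    pixels=np.asarray(d["pixels"], dtype=np.int32),
                    centroid=tuple(d["centroid"]),
                    bbox=tuple(d["bbox"]),
                    mean_intensity=d["mean_intensity"],
                    max_intensity=d["max_intensity"],
                )
            )
    return out


def save_rois(
    rois: Sequence[MultiFrameROI],
    json_path: str | Path,
    label_path: str | Path | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> None:
    records = [
        {
            "id": r.id,
            "centroid_px": list(r.centroid),
            "bbox": list(r.bbox),
            "area_px": r.area,
            "n_appearances": r.n_appearances,
            "frame_indices": r.frame_indices.tolist(),
            "mask": r.mask.tolist(),
        }
        for r in rois
    ]
    with open(json_path, "w") as fh:
        json.dump(records, fh)
    if label_path is not None:
        if frame_shape is None:
            raise ValueError("frame_shape required to write a label image")
        labels = np.zeros(frame_shape, dtype=np.uint16)
        for r in rois:
            labels[r.mask[:, 0], r.mask[:, 1]] = r.id
        tifffile.imwrite(str(label_path), labels, photometric="minisblack")


def load_rois(json_path: str | Path) -> list[MultiFrameROI]:
    with open(json_path) as fh:
        records = json.load(fh)
    return [
        MultiFrameROI(
            id=d["id"],
            mask=np.asarray(d["mask"], dtype=np.int32),
            centroid=tuple(d["centroid_px"]),
            bbox=tuple(d["bbox"]),
            frame_indices=np.asarray(d["frame_indices"], dtype=np.int64),
            n_appearances=d["n_appearances"],
        )
        for d in records
    ]


def save_ground_truth(gt: GroundTruth, json_path: str | Path, label_path: str | Path | None = None) -> None:
    data = {
        "cell_centers": gt.cell_centers.tolist(),
        "event_times": [e.tolist() for e in gt.event_times],
        "modulation_label": gt.modulation_label.tolist(),
        "motion_trace": gt.motion_trace.tolist(),
        "trial_tone_onset_s": gt.trial_schedule.tone_onset_s.tolist(),
        "trial_outcomes": gt.trial_outcomes.tolist(),
        "session_duration_s": gt.session_duration_s,
    }
    with open(json_path, "w") as fh:
        json.dump(data, fh)
    if label_path is not None:
        tifffile.imwrite(str(label_path), gt.cell_labels, photometric="minisblack")
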