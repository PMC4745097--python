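"""End-to-end orchestration: simulate → preprocess → detect → merge →
extract → behavior → analyze → spatial, with a deterministic manifest.

Every stage is also runnable standalone through the CLI on the declared
file formats; this module wires them together in memory and records the
per-stage summary numbers.  The manifest contains no wall-clock data, so a
rerun with the same config and seed reproduces it bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .artifacts import save_ground_truth, save_rois, save_sfrois
from .behavior import classify_trials, performance_percent
from .config import PipelineConfig
from .detect import detect_rois
from .merge import cluster_rois, filter_separated
from .preprocess import correct_sequence
from .spatial import adjacency_counts, resampling_test
from .synth import make_ground_truth, render_eyelid, render_movie
from .taskstats import classify_all, summarize_population
from .traces import compute_snr, extract_traces, normalize_traces, photobleaching_percent
from .video import compute_pixel_stats, field_of_view, reduce_bit_depth, write_tiff

log = logging.getLogger("widecal")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    write_movies: bool = True,
) -> dict[str, Any]:
    """Run the full pipeline on a simulated session; return the manifest.

    With ``outdir`` set, every intermediate artifact is written there.  The
    trial-aligned modulation analysis uses the trials whose analysis windows
    fit inside the rendered movie; when fewer than two correct trials fit
    (short desk-scale movies), the modulation and spatial stages are skipped
    and flagged in the manifest.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "widecal_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }

    stage = "simulate"
    try:
        gt = make_ground_truth(config.sim)
        movie = render_movie(gt, config.sim)
        eyelid = render_eyelid(gt, config.sim)
        manifest["simulate"] = {
            "n_frames": movie.n_frames,
            "frame_shape": list(movie.frame_shape),
            "field_of_view_mm": list(field_of_view(movie)),
            "n_cells": gt.n_cells,
            "n_trials": gt.trial_schedule.n_trials,
        }
        if outdir is not None:
            if write_movies:
                write_tiff(movie, outdir / "movie.tif")
            save_ground_truth(gt, outdir / "ground_truth.json", outdir / "cell_labels.tif")
            eyelid.to_dataframe().to_csv(outdir / "eyelid.csv", index=False)

        stage = "preprocess"
        corrected, disp = correct_sequence(movie, config.registration)
        mean_disp, sd_disp = disp.summary
        manifest["preprocess"] = {
            "mean_displacement_um_per_frame": mean_disp,
            "sd_displacement_um_per_frame": sd_disp,
        }
        stats = compute_pixel_stats(corrected)
        bleach = photobleaching_percent(corrected, end_frames=1)
        manifest["preprocess"]["bleach_percent"] = bleach
        if outdir is not None:
            disp.to_dataframe().to_csv(outdir / "shifts.csv", index=False)
            if write_movies:
                corrected16 = corrected.with_frames(
                    np.clip(np.floor(corrected.frames + 0.5), 0, 65535).astype(np.uint16)
                )
                write_tiff(corrected16, outdir / "corrected.tif")
                write_tiff(reduce_bit_depth(corrected16), outdir / "reduced8.tif")

        stage = "detect"
        sfrois = detect_rois(corrected, stats, config.detection)
        n_sfrois = sum(len(f) for f in sfrois)
        manifest["detect"] = {"n_single_frame_rois": n_sfrois}
        if outdir is not None:
            save_sfrois(sfrois, outdir / "sfrois.jsonl")

        stage = "merge"
        merged = cluster_rois(sfrois, config.merge, frame_shape=movie.frame_shape)
        rois = filter_separated(merged, config.merge)
        manifest["merge"] = {
            "n_rois_merged": len(merged),
            "n_rois_after_overlap_filter": len(rois),
        }
        if outdir is not None:
            save_rois(rois, outdir / "rois.json", outdir / "rois_labels.tif", movie.frame_shape)

        stage = "extract"
        traces = extract_traces(corrected, rois) if rois else None
        if traces is not None:
            normalize_traces(traces)
            quality = compute_snr(corrected, rois, traces)
            manifest["extract"] = {
                "n_traces": traces.n_rois,
                "snr_mean": float(quality.snr.mean()),
                "snr_sem": float(quality.snr.std(ddof=1) / np.sqrt(len(quality.snr)))
                if len(quality.snr) > 1
                else 0.0,
                "noise_sigma": quality.noise_sigma,
            }
            if outdir is not None:
                traces.to_dataframe().to_csv(outdir / "traces.csv", index=False)
                with open(outdir / "quality.json", "w") as fh:
                    json.dump(
                        {"snr": quality.snr.tolist(), "noise_sigma": quality.noise_sigma,
                         "bleach_percent": bleach},
                        fh,
                    )
        else:
            manifest["extract"] = {"n_traces": 0}

        stage = "behavior"
        scored = classify_trials(eyelid, gt.trial_schedule, config.behavior)
        manifest["behavior"] = {
            "performance_percent": performance_percent(scored),
            "n_correct": int(np.sum(scored.outcome == "correct")),
            "n_incorrect": int(np.sum(scored.outcome == "incorrect")),
        }
        if outdir is not None:
            scored.to_csv(outdir / "events.csv")

        stage = "analyze"
        analyzed = False
        if traces is not None:
            window = (config.analysis.baseline_window_s[0], config.analysis.task_window_s[1])
            from .taskstats import align_trials

            _, included = align_trials(
                traces.dff[0], scored, window, traces.frame_rate, corrected.t0
            )
            n_correct_fit = int(np.sum(np.asarray(scored.outcome)[included] == "correct"))
            if n_correct_fit >= 2:
                results = classify_all(
                    traces.dff, scored, config.analysis, traces.frame_rate, corrected.t0
                )
                labels = [r.label for r in results]
                summary = summarize_population(labels, config.analysis.percent_decimals)
                manifest["analyze"] = {
                    "summary": summary,
                    "n_trials_in_movie": int(len(included)),
                    "n_correct_trials_used": n_correct_fit,
                }
                analyzed = True
                if outdir is not None:
                    import pandas as pd

                    pd.DataFrame(
                        {
                            "roi_id": traces.roi_ids,
                            "p_value": [r.p_value for r in results],
                            "t_stat": [r.t_stat for r in results],
                            "label": labels,
                            "mean_task_minus_baseline": [
                                r.mean_task_minus_baseline for r in results
                            ],
                        }
                    ).to_csv(outdir / "modulation.csv", index=False)
                    with open(outdir / "summary.json", "w") as fh:
                        json.dump(summary, fh, indent=2)
        if not analyzed:
            manifest["analyze"] = {"skipped": "fewer than 2 correct trials fit the movie"}
            labels = []

        stage = "spatial"
        if analyzed and rois:
            pitch = movie.pixel_pitch
            points = np.asarray([r.centroid for r in rois], dtype=float) * pitch
            lab = np.asarray(labels, dtype=object)
            spatial_out: dict[str, Any] = {
                "adjacency": adjacency_counts(points, lab, config.spatial)
            }
            pos_idx = np.nonzero(lab == "positive")[0]
            if len(pos_idx) >= 2 and len(points) > len(pos_idx):
                res = resampling_test(points, pos_idx, config.spatial)
                spatial_out["resampling"] = {
                    "observed_median_um": res.observed_median_um,
                    "null_mean_um": res.null_mean_um,
                    "null_sd_um": res.null_sd_um,
                    "p_value": res.p_value,
                    "tail": res.tail,
                }
            manifest["spatial"] = spatial_out
            if outdir is not None:
                with open(outdir / "spatial.json", "w") as fh:
                    json.dump(spatial_out, fh, indent=2)
        else:
            manifest["spatial"] = {"skipped": "modulation labels unavailable"}
    except Exception as exc:  # noqa: BLE001
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    if outdir is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
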