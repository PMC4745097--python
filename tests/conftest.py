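import numpy as np
import pytest

from widecal import SimParams, make_ground_truth, render_movie


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    """A seconds-scale session used by several suites."""
    return SimParams(
        frame_height=96,
        frame_width=96,
        n_frames=80,
        n_cells=4,
        soma_radius=4.0,
        n_trials=3,
        n_correct=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_movie_params() -> SimParams:
    """Noise-, motion-, bleach- and vignette-free rendering conditions."""
    return SimParams(
        frame_height=96,
        frame_width=96,
        n_frames=200,
        n_cells=3,
        soma_radius=4.0,
        read_noise_sigma=0.0,
        shot_noise=False,
        quantize=False,
        resp_amplitude=0.0,
        jump_rate=0.0,
        illum_amplitude=0.0,
        bleach_end_fraction=1.0,
        n_trials=2,
        n_correct=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def registration_movie():
    """Noise-free 128x128 movie with known sinusoidal + jump motion."""
    params = SimParams(
        frame_height=128,
        frame_width=128,
        n_frames=100,
        n_cells=8,
        soma_radius=4.5,
        read_noise_sigma=0.0,
        shot_noise=False,
        quantize=False,
        jump_rate=0.05,
        bleach_end_fraction=1.0,
        n_trials=2,
        n_correct=1,
        seed=5,
    )
    gt = make_ground_truth(params)
    movie = render_movie(gt, params)
    return params, gt, movie


def match_cells(centers: np.ndarray, rois, radius: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected ROI centroids to planted
    centers within ``radius`` px.  Returns (hits, n_cells, n_rois)."""
    used: set[int] = set()
    hits = 0
    for roi in rois:
        d = np.hypot(*(centers - np.asarray(roi.centroid)).T)
        order = np.argsort(d)
        for j in order:
            if d[j] > radius:
                break
            if j not in used:
                used.add(int(j))
                hits += 1
                break
    return hits, len(centers), len(rois)
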