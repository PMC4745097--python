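"""Spatial statistics on ROI centroids.

Tests whether a labeled subpopulation (e.g. positively modulated cells) is
distributed more sparsely than chance: the median pairwise distance of the
subset is compared against a null distribution built by repeatedly drawing
equal-size subsets from the whole population.  Local structure is
summarized by 50 µm adjacency counts between modulation classes, compared
with a tie-corrected Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist, pdist

LABELS = ("positive", "negative", "none")


@dataclass
class SpatialParams:
    n_resamples: int = 500
    radius_um: float = 50.0
    seed: int | None = None
    tail: Literal["upper", "lower"] = "upper"

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.tail not in ("upper", "lower"):
            raise ValueError("tail must be 'upper' or 'lower'")


@dataclass
class SpatialTestResult:
    observed_median_um: float
    null_medians: np.ndarray
    p_value: float
    null_mean_um: float
    null_sd_um: float
    tail: str
    n_resamples: int

    def format_p(self) -> str:
        if self.p_value == 0:
            return f"< {1.0 / self.n_resamples:g}"
        return f"{self.p_value:g}"


def pairwise_median_distance(points: np.ndarray) -> float:
    """Median of all C(n,2) pairwise Euclidean distances (µm in, µm out)."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    return float(np.median(pdist(points)))


def resampling_test(
    points: np.ndarray,
    subset_indices: Sequence[int],
    params: SpatialParams | None = None,
) -> SpatialTestResult:
    """Resampling test on the median pairwise distance of a subset.

    Each of ``n_resamples`` draws takes ``|subset|`` points without
    replacement from the whole population (with replacement between draws)
    and records the median pairwise distance.  With ``tail='upper'`` the
    p-value is the fraction of null values at or above the observed
    statistic (subset sparser than chance); ``tail='lower'`` counts the
    null values strictly below it.  No +1 smoothing is applied, so p = 0
    should be displayed as "< 1/n_resamples" (see ``format_p``).
    """
    params = params or SpatialParams()
    points = np.asarray(points, dtype=np.float64)
    subset_indices = np.asarray(subset_indices, dtype=np.int64)
    if len(subset_indices) < 2:
        raise ValueError("subset must contain at least 2 points")
    if subset_indices.max() >= len(points) or subset_indices.min() < 0:
        raise ValueError("subset indices out of range")
    k = len(subset_indices)
    if k == len(points):
        warnings.warn("subset equals the whole population; the test is degenerate")
    observed = pairwise_median_distance(points[subset_indices])
    rng = np.random.default_rng(params.seed)
    null = np.empty(params.n_resamples)
    for i in range(params.n_resamples):
        draw = rng.choice(len(points), size=k, replace=False)
        null[i] = pairwise_median_distance(points[draw])
    if params.tail == "upper":
        p = float(np.count_nonzero(null >= observed)) / params.n_resamples
    else:
        p = float(np.count_nonzero(null < observed)) / params.n_resamples
    return SpatialTestResult(
        observed_median_um=observed,
        null_medians=null,
        p_value=p,
        null_mean_um=float(null.mean()),
        null_sd_um=float(null.std(ddof=1)),
        tail=params.tail,
        n_resamples=params.n_resamples,
    )


def adjacency_counts(
    points: np.ndarray,
    labels: Sequence[str],
    params: SpatialParams | None = None,
) -> dict[str, dict[str, dict[str, float]]]:
    """Mean ± SD neighbour counts within radius_um, by modulation class.

    For every reference ROI the neighbours (centre distance <= radius,
    self excluded) of each label are counted; counts are aggregated as mean
    and sample SD over all reference ROIs sharing the reference label.
    Returns table[ref_label][neighbor_label] = {"mean": ..., "sd": ...,
    "n_ref": ...}; classes with no reference ROI hold NaNs.
    """
    params = params or SpatialParams()
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(list(labels), dtype=object)
    if len(points) != len(labels):
        raise ValueError("points and labels must align")
    n = len(points)
    if n:
        close = cdist(points, points) <= params.radius_um
        np.fill_diagonal(close, False)
    table: dict[str, dict[str, dict[str, float]]] = {}
    for ref in LABELS:
        ref_idx = np.nonzero(labels == ref)[0]
        table[ref] = {}
        for nb in LABELS:
            if len(ref_idx) == 0:
                table[ref][nb] = {"mean": float("nan"), "sd": float("nan"), "n_ref": 0}
                continue
            counts = close[ref_idx][:, labels == nb].sum(axis=1)
            sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
            table[ref][nb] = {
                "mean": float(counts.mean()),
                "sd": sd,
                "n_ref": int(len(ref_idx)),
            }
    return table


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney rank-sum with midranks and tie-corrected
    normal approximation; two-sided p.

    Returns (z, p).  If every value across both groups is identical the
    statistic is degenerate and (0, 1) is returned.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
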