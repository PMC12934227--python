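"""Skull thickness from inner/outer surface point clouds.

For every point sampled on the outer skull surface, thickness is the mean
Euclidean distance to its k nearest neighbours (default k=30) among the
points sampled on the inner surface; averaging over k neighbours suppresses
sampling outliers. Per-point values outside physical bounds (default
0.5–12 mm, inclusive) are flagged out-of-bounds, and the scan-level summary
is the median over in-bounds points — thickness distributions over a skull
are typically skewed, so the median is the robust scan statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyAfterFilterError, ParameterError
from .mesh import SurfacePointCloud, TriangleMesh, sample_surface

logger = logging.getLogger(__name__)

DEFAULT_K = 30
DEFAULT_BOUNDS = (0.5, 12.0)
DEFAULT_N_POINTS = 500_000

#: out-of-bounds share above which a scan is flagged as a suspect segmentation
EXCLUDED_FRACTION_WARNING = 0.20


@dataclass
class ThicknessCloud:
    """Per-point thickness over the outer surface."""

    outer_points: np.ndarray      # (N, 3) mm
    thickness: np.ndarray         # (N,) mm
    in_bounds: np.ndarray         # (N,) bool
    k: int = DEFAULT_K
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    region: np.ndarray | None = field(default=None)  # (N,) int labels, 0 = unlabeled

    def __len__(self) -> int:
        return len(self.thickness)


@dataclass
class ThicknessSummary:
    median_mm: float
    n_total: int
    n_in_bounds: int

    @property
    def fraction_excluded(self) -> float:
        return 1.0 - self.n_in_bounds / self.n_total if self.n_total else 0.0


def knn_mean_distance(
    outer: SurfacePointCloud | np.ndarray,
    inner: SurfacePointCloud | np.ndarray,
    k: int = DEFAULT_K,
) -> np.ndarray:
    """Mean distance from each outer point to its k nearest inner points (mm).

    The inner cloud must contain at least ``k`` points; a smaller cloud is a
    hard error rather than a silent reduction of ``k``, so results are never
    quietly computed under different conditions than requested. The result is
    independent of the ordering of the inner cloud.
    """
    outer_pts = outer.points if isinstance(outer, SurfacePointCloud) else np.asarray(outer, float)
    inner_pts = inner.points if isinstance(inner, SurfacePointCloud) else np.asarray(inner, float)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if len(inner_pts) < k:
        raise ParameterError(
            f"inner cloud has {len(inner_pts)} points but k={k} neighbours were requested"
        )
    tree = cKDTree(inner_pts)
    dist, _ = tree.query(outer_pts, k=k)
    if k == 1:
        return np.atleast_1d(dist).astype(float)
    return dist.mean(axis=1)


def apply_bounds(
    distances: np.ndarray,
    lower: float = DEFAULT_BOUNDS[0],
    upper: float = DEFAULT_BOUNDS[1],
) -> np.ndarray:
    """Flag which per-point thickness values lie inside [lower, upper] (inclusive)."""
    if lower > upper:
        raise ParameterError(f"lower bound {lower} exceeds upper bound {upper}")
    d = np.asarray(distances, dtype=float)
    return (d >= lower) & (d <= upper)


def summarize_thickness(cloud: ThicknessCloud) -> ThicknessSummary:
    """Median thickness over in-bounds points; errors if the filter left nothing."""
    n_total = len(cloud)
    kept = cloud.thickness[cloud.in_bounds]
    if kept.size == 0:
        raise EmptyAfterFilterError(
            f"no thickness values within bounds {cloud.bounds} (n={n_total})"
        )
    summary = ThicknessSummary(
        median_mm=float(np.median(kept)),
        n_total=n_total,
        n_in_bounds=int(kept.size),
    )
    if summary.fraction_excluded > EXCLUDED_FRACTION_WARNING:
        logger.warning(
            "%.1f%% of points outside bounds %s — segmentation may be unreliable",
            100 * summary.fraction_excluded,
            cloud.bounds,
        )
    return summary


def measure_skull(
    inner_mesh: TriangleMesh,
    outer_mesh: TriangleMesh,
    n_points: int = DEFAULT_N_POINTS,
    k: int = DEFAULT_K,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    seed: int = 0,
) -> tuple[ThicknessCloud, ThicknessSummary]:
    """End-to-end skull thickness: sample both surfaces, probe inner from outer.

    Samples ``n_points`` on each surface (outer with ``seed``, inner with
    ``seed + 1`` so the clouds are independent but jointly deterministic),
    averages the 30-NN distances, applies the physical bounds and summarizes.
    """
    outer_cloud = sample_surface(outer_mesh, n_points, seed=seed)
    inner_cloud = sample_surface(inner_mesh, n_points, seed=seed + 1)
    thickness = knn_mean_distance(outer_cloud, inner_cloud, k=k)
    flags = apply_bounds(thickness, *bounds)
    cloud = ThicknessCloud(
        outer_points=outer_cloud.points,
        thickness=thickness,
        in_bounds=flags,
        k=k,
        bounds=bounds,
    )
    return cloud, summarize_thickness(cloud)
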