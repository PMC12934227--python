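"""Supratentorial restriction and regional partition of thickness clouds.

The calvaria is split into frontal, parietal, occipital and temporal bone
territories using an integer label volume (a calvarial atlas in a standard
space such as MNI) carried with its voxel-to-world affine. Because such
atlases are defined on the bone interior, the labels are first spread
outward by per-label Gaussian smoothing (sigma 8 mm by default) so the
outer-surface point cloud falls entirely inside labelled territory. Analysis
is restricted to points superior to an axial exclusion plane (the world-z of
slice 28 of the 2 mm standard grid, i.e. z = -16 mm under the usual affine),
removing the skull base and orbitofrontal regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyAfterFilterError, ParameterError
from .thickness import ThicknessCloud

logger = logging.getLogger(__name__)

REGION_NAMES = {1: "frontal", 2: "parietal", 3: "occipital", 4: "temporal"}
UNLABELED = 0

DEFAULT_DILATION_SIGMA_MM = 8.0
DEFAULT_EXCLUSION_SLICE = 28  # axial slice index on the 2 mm standard grid
#: smoothed-response floor below which a voxel stays unlabeled after dilation
DILATION_FLOOR = 0.01
#: regions holding less than this share of classified points are unreliable
DEFAULT_MIN_FRACTION = 0.01

#: voxel-to-world affine of the standard 2 mm (MNI152) grid
MNI152_2MM_AFFINE = np.array(
    [
        [-2.0, 0.0, 0.0, 90.0],
        [0.0, 2.0, 0.0, -126.0],
        [0.0, 0.0, 2.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass
class RegionAtlas:
    """Integer label volume (0 unlabeled, 1-4 calvarial bones) with affine."""

    label_grid: np.ndarray
    affine: np.ndarray
    dilation_sigma_mm: float = DEFAULT_DILATION_SIGMA_MM

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ParameterError("atlas affine is singular")
        labels = np.unique(self.label_grid)
        if labels.min() < 0 or labels.max() > max(REGION_NAMES):
            raise ParameterError(f"labels must lie in 0..{max(REGION_NAMES)}, got {labels}")

    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class RegionalSummary:
    """Per-region median thickness with reliability flags.

    ``per_region`` maps region name -> (median_mm, n_points, relative_surface);
    ``unreliable`` lists regions whose share of classified points fell below
    ``min_fraction`` (they are excluded from downstream slope analysis).
    """

    per_region: dict[str, tuple[float, int, float]]
    unreliable: list[str]
    min_fraction: float
    n_unlabeled: int


def load_atlas(path: str | Path, dilation_sigma_mm: float = DEFAULT_DILATION_SIGMA_MM) -> RegionAtlas:
    """Read an integer label atlas from NIfTI-1 (affine: sform if valid, else qform)."""
    img = nib.load(str(path))
    if int(img.header["sform_code"]) > 0:
        affine = img.get_sform()
        logger.info("atlas affine taken from sform")
    elif int(img.header["qform_code"]) > 0:
        affine = img.get_qform()
        logger.info("atlas affine taken from qform")
    else:
        affine = img.affine
        logger.warning("atlas has neither valid sform nor qform; using fallback affine")
    grid = np.asarray(img.dataobj).astype(np.int32)
    return RegionAtlas(label_grid=grid, affine=affine, dilation_sigma_mm=dilation_sigma_mm)


def save_atlas(atlas: RegionAtlas, path: str | Path) -> Path:
    img = nib.Nifti1Image(atlas.label_grid.astype(np.int16), atlas.affine)
    nib.save(img, str(path))
    return Path(path)


def slice_to_world_z(slice_index: int, affine: np.ndarray | None = None) -> float:
    """World z (mm) of axial slice ``k`` under the given voxel-to-world affine.

    Defaults to the standard 2 mm grid affine (z = 2k - 72; slice 28 -> -16 mm).
    The atlas header affine, when available, is authoritative.
    """
    aff = MNI152_2MM_AFFINE if affine is None else np.asarray(affine, float)
    return float((aff @ np.array([0.0, 0.0, float(slice_index), 1.0]))[2])


def filter_superior(cloud: ThicknessCloud, plane_z_mm: float) -> ThicknessCloud:
    """Keep only points with world z >= plane_z_mm (supratentorial restriction)."""
    keep = cloud.outer_points[:, 2] >= plane_z_mm
    if not keep.any():
        raise EmptyAfterFilterError(f"no points superior to z = {plane_z_mm} mm")
    return ThicknessCloud(
        outer_points=cloud.outer_points[keep],
        thickness=cloud.thickness[keep],
        in_bounds=cloud.in_bounds[keep],
        k=cloud.k,
        bounds=cloud.bounds,
        region=None if cloud.region is None else cloud.region[keep],
    )


def dilate_atlas(atlas: RegionAtlas, sigma_mm: float | None = None) -> RegionAtlas:
    """Spread each label outward by Gaussian smoothing of its binary mask.

    Every originally unlabeled voxel takes the label whose smoothed response
    is maximal there, provided that response exceeds a small floor (so the
    spread stays local); originally labelled voxels are never changed. Ties
    go to the lowest label id. ``sigma_mm == 0`` is the identity.
    """
    sigma = atlas.dilation_sigma_mm if sigma_mm is None else sigma_mm
    if sigma < 0:
        raise ParameterError("dilation sigma must be >= 0")
    if sigma == 0:
        return atlas
    sigma_vox = sigma / atlas.voxel_size_mm()
    labels = sorted(int(l) for l in np.unique(atlas.label_grid) if l != UNLABELED)
    if not labels:
        return atlas
    responses = np.stack(
        [ndimage.gaussian_filter((atlas.label_grid == lab).astype(float), sigma_vox) for lab in labels]
    )
    # normalize each label's response to its own peak so the floor bounds the
    # spread (~3 sigma) regardless of how thick the labelled territory is
    peaks = responses.reshape(len(labels), -1).max(axis=1)
    responses /= np.where(peaks > 0, peaks, 1.0)[:, None, None, None]
    best = np.argmax(responses, axis=0)  # first max -> lowest label id wins ties
    best_val = np.take_along_axis(responses, best[None], axis=0)[0]
    new_grid = atlas.label_grid.copy()
    fill = (atlas.label_grid == UNLABELED) & (best_val > DILATION_FLOOR)
    new_grid[fill] = np.asarray(labels)[best[fill]]
    return replace(atlas, label_grid=new_grid, dilation_sigma_mm=sigma)


def classify_points(cloud: ThicknessCloud, atlas: RegionAtlas) -> ThicknessCloud:
    """Label each point with the atlas region of its containing voxel.

    Points are mapped through the inverse affine to the nearest voxel centre;
    points outside the grid (or in unlabeled voxels) get label 0. The cloud
    and atlas must share a world space — registration is an upstream concern.
    """
    inv = np.linalg.inv(atlas.affine)
    homog = np.c_[cloud.outer_points, np.ones(len(cloud))]
    vox = np.rint((homog @ inv.T)[:, :3]).astype(np.int64)
    shape = np.asarray(atlas.label_grid.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    labels = np.zeros(len(cloud), dtype=np.int32)
    idx = vox[inside]
    labels[inside] = atlas.label_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    return replace(cloud, region=labels)


def regional_medians(
    cloud: ThicknessCloud, min_fraction: float = DEFAULT_MIN_FRACTION
) -> RegionalSummary:
    """Median thickness per region over in-bounds points.

    ``relative_surface`` is each region's share of classified points; regions
    under ``min_fraction`` are flagged unreliable (in practice the temporal
    bones, which occupy a sliver of the supratentorial mask).
    """
    if cloud.region is None:
        raise ParameterError("cloud has no region labels; run classify_points first")
    classified = cloud.region != UNLABELED
    n_classified = int(classified.sum())
    if n_classified == 0:
        raise EmptyAfterFilterError("no points fell inside labelled atlas territory")
    per_region: dict[str, tuple[float, int, float]] = {}
    unreliable: list[str] = []
    for label, name in REGION_NAMES.items():
        mask = cloud.region == label
        n_pts = int(mask.sum())
        if n_pts == 0:
            continue
        share = n_pts / n_classified
        vals = cloud.thickness[mask & cloud.in_bounds]
        median = float(np.median(vals)) if vals.size else float("nan")
        per_region[name] = (median, n_pts, share)
        if share < min_fraction:
            unreliable.append(name)
            logger.warning(
                "region %s holds %.2f%% of classified points (< %.0f%%): flagged unreliable",
                name, 100 * share, 100 * min_fraction,
            )
    return RegionalSummary(
        per_region=per_region,
        unreliable=unreliable,
        min_fraction=min_fraction,
        n_unlabeled=int(len(cloud) - n_classified),
    )
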