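"""Synthetic skull phantoms and longitudinal cohorts with known ground truth.

The study conditions this package targets — inner/outer skull surface pairs
2–12 mm apart enclosing 1000–1700 mL, and three-group longitudinal cohorts
(MLD, MS, control) with group-specific ICV and thickness slopes — are not
publicly deposited, so everything here is generated analytically:

* concentric-shell phantoms whose inner surface is a subdivided icosphere
  (optionally anisotropically scaled to an ellipsoid, or halved) and whose
  outer surface is the inner vertices displaced along exact outward normals
  by a configurable gap field, so the true thickness field and the true
  enclosed volume are known in closed form;
* an inward-remodeling simulator that moves the inner table inward while
  the outer table stays fixed, thickening the skull and shrinking the
  intracranial volume by the thin-shell amount A*delta;
* a cohort generator drawing per-subject intercepts and per-stratum slopes
  from configurable distributions, with an optional coupling mode in which
  ICV loss is exactly -gain * thickness gain at the latent level.

The default cohort template (data/cohort_default.json) encodes group sizes
and slope mean/sd matching published three-group longitudinal skull
morphometry; it is configuration data, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import ParameterError
from .mesh import TriangleMesh, enclosed_volume
from .regions import RegionAtlas
from .thickness import measure_skull

MM3_PER_ML = 1000.0

# angular-sector layout (degrees): top cap parietal, then azimuthal wedges
PARIETAL_POLAR_DEG = 45.0
FRONTAL_AZ_DEG = (30.0, 150.0)      # around +y
OCCIPITAL_AZ_DEG = (-150.0, -30.0)  # around -y


# --------------------------------------------------------------------------
# shell phantoms
# --------------------------------------------------------------------------

@dataclass
class SkullPhantom:
    """Inner/outer shell pair with analytic truth attached."""

    inner_mesh: TriangleMesh
    outer_mesh: TriangleMesh
    true_icv_ml: float
    thickness_field: object          # callable (N,3) unit dirs -> (N,) mm
    shape: str                       # "sphere" | "ellipsoid" | "hemisphere"
    axes_mm: tuple[float, float, float]
    seed: int
    inner_normals: np.ndarray = field(repr=False, default=None)
    inward_offset_mm: float = 0.0    # cumulative inner-table displacement

    def true_median_thickness(self, n_dirs: int = 20000) -> float:
        """Area-weighted median of the true gap field (quadrature on the sphere)."""
        rng = np.random.default_rng(12345)
        u = rng.normal(size=(n_dirs, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        if self.shape == "hemisphere":
            u[:, 2] = np.abs(u[:, 2])
        gaps = np.asarray(self.thickness_field(u), float)
        if self.shape == "ellipsoid":
            # area element of x = (a u1, b u2, c u3):  |n| dA with
            # n = (bc u1, ac u2, ab u3); weight uniform sphere dirs by |n|
            a, b, c = self.axes_mm
            w = np.linalg.norm(u * np.array([b * c, a * c, a * b]), axis=1)
            order = np.argsort(gaps)
            cdf = np.cumsum(w[order])
            return float(gaps[order][np.searchsorted(cdf, 0.5 * cdf[-1])])
        return float(np.median(gaps))


def _unit_shape(shape: str, subdivision: int) -> trimesh.Trimesh:
    sphere = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    if shape in ("sphere", "ellipsoid"):
        return sphere
    if shape == "hemisphere":
        half = trimesh.intersections.slice_mesh_plane(
            sphere, plane_normal=[0, 0, 1], plane_origin=[0, 0, 0], cap=False
        )
        half.merge_vertices()  # slicing leaves duplicate vertices along the cut
        return _fan_cap(half)
    raise ParameterError(f"unknown phantom shape {shape!r}")


def _fan_cap(open_mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close a single planar boundary loop with a fan to its centroid.

    Boundary edges occur in exactly one face, with winding inherited from it,
    so fanning (centre, v1, v0) over each directed boundary edge yields an
    outward-oriented cap consistent with the rest of the surface.
    """
    faces = np.asarray(open_mesh.faces)
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    _, first_idx, counts = np.unique(
        undirected, axis=0, return_index=True, return_counts=True
    )
    boundary = directed[first_idx[counts == 1]]
    vertices = np.asarray(open_mesh.vertices)
    centre = vertices[np.unique(boundary)].mean(axis=0)
    new_vertices = np.vstack([vertices, centre])
    c = len(vertices)
    cap_faces = np.c_[np.full(len(boundary), c), boundary[:, 1], boundary[:, 0]]
    return trimesh.Trimesh(
        vertices=new_vertices, faces=np.vstack([faces, cap_faces]), process=False
    )


def _ellipsoid_normals(unit_vertices: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Exact outward unit normals of x = axes * u at parameter u on the unit sphere."""
    n = unit_vertices / axes  # gradient of (x/a)^2+(y/b)^2+(z/c)^2
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def make_shell_phantom(
    shape: str = "sphere",
    inner_axes_mm: float | tuple[float, float, float] = 80.0,
    gap_field: float | object = 3.0,
    subdivision: int = 4,
    jitter_sd_mm: float = 0.0,
    seed: int = 0,
) -> SkullPhantom:
    """Build a concentric-shell skull phantom with analytic ground truth.

    Parameters
    ----------
    shape
        ``sphere``, ``ellipsoid`` or ``hemisphere`` (flat-capped half shell).
    inner_axes_mm
        Radius, or (a, b, c) semi-axes, of the inner surface; the plausible
        cranial range is roughly 50-110 mm.
    gap_field
        Constant gap in mm, or a callable mapping (N, 3) unit directions to
        per-vertex gaps. Must be strictly positive everywhere.
    jitter_sd_mm
        Gaussian noise added to the outer-vertex displacement along the
        normal, emulating segmentation noise.
    """
    axes = np.broadcast_to(np.asarray(inner_axes_mm, float), (3,)).copy()
    if np.any(axes < 50.0) or np.any(axes > 110.0):
        raise ParameterError(f"semi-axes {axes} outside the plausible cranial range 50-110 mm")
    if shape == "sphere" and np.ptp(axes) > 0:
        raise ParameterError("sphere requires equal semi-axes; use shape='ellipsoid'")
    base = _unit_shape("hemisphere" if shape == "hemisphere" else "sphere", subdivision)
    unit_v = np.asarray(base.vertices, float)
    on_dome = np.linalg.norm(unit_v, axis=1) > 0.5  # exclude the flat cap of a hemisphere
    inner_vertices = unit_v * axes
    inner = TriangleMesh(inner_vertices, np.asarray(base.faces))

    gap_fn = (lambda dirs, g=float(gap_field): np.full(len(dirs), g)) if np.isscalar(gap_field) else gap_field
    dirs = np.where(on_dome[:, None], unit_v, np.array([0.0, 0.0, 1.0]))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    gaps = np.asarray(gap_fn(dirs), float)
    if np.any(gaps <= 0):
        raise ParameterError("gap_field must be strictly positive everywhere")
    if jitter_sd_mm > 0 and gaps.min() <= 4 * jitter_sd_mm:
        raise ParameterError("minimum gap must exceed 4x the jitter sd to keep the shells disjoint")

    normals = _ellipsoid_normals(unit_v, axes)
    disp = gaps.copy()
    if jitter_sd_mm > 0:
        disp += np.random.default_rng(seed).normal(0.0, jitter_sd_mm, size=len(gaps))
    outer_vertices = inner_vertices.copy()
    outer_vertices[on_dome] += (normals * disp[:, None])[on_dome]
    outer = TriangleMesh(outer_vertices, np.asarray(base.faces))

    a, b, c = axes
    if shape == "hemisphere":
        true_icv = (2.0 / 3.0) * np.pi * a * b * c / MM3_PER_ML
    else:
        true_icv = (4.0 / 3.0) * np.pi * a * b * c / MM3_PER_ML
    return SkullPhantom(
        inner_mesh=inner,
        outer_mesh=outer,
        true_icv_ml=float(true_icv),
        thickness_field=gap_fn,
        shape=shape,
        axes_mm=tuple(axes),
        seed=seed,
        inner_normals=normals,
    )


def evolve_inward(phantom: SkullPhantom, delta_mm: float, n_steps: int) -> list[SkullPhantom]:
    """Remodel the skull inward: the inner table recedes, the outer stays put.

    Each step displaces every inner-mesh vertex by ``delta_mm`` along its
    inward normal; thickness grows by exactly ``delta_mm`` per step and the
    enclosed volume shrinks by about surface_area * delta (thin-shell
    identity). Returns the sequence of ``n_steps`` evolved phantoms.
    """
    if delta_mm < 0:
        raise ParameterError("delta_mm must be >= 0")
    total = phantom.inward_offset_mm + delta_mm * n_steps
    if total >= min(phantom.axes_mm) / 2.0:
        raise ParameterError(
            f"cumulative inward displacement {total:.1f} mm risks self-intersection "
            f"(limit {min(phantom.axes_mm) / 2:.1f} mm)"
        )
    out: list[SkullPhantom] = []
    current = phantom
    for _ in range(n_steps):
        offset = current.inward_offset_mm + delta_mm
        inner_vertices = phantom.inner_mesh.vertices - phantom.inner_normals * offset
        inner = TriangleMesh(inner_vertices, phantom.inner_mesh.faces.copy())
        if phantom.shape == "sphere":
            r = phantom.axes_mm[0] - offset
            true_icv = (4.0 / 3.0) * np.pi * r**3 / MM3_PER_ML
        else:
            true_icv = enclosed_volume(inner)
        base_field = phantom.thickness_field
        current = replace(
            phantom,
            inner_mesh=inner,
            true_icv_ml=float(true_icv),
            thickness_field=(lambda dirs, off=offset, f=base_field: np.asarray(f(dirs), float) + off),
            inward_offset_mm=offset,
        )
        out.append(current)
    return out


# --------------------------------------------------------------------------
# angular-sector regional truth
# --------------------------------------------------------------------------

def sector_labels(points: np.ndarray) -> np.ndarray:
    """Analytic calvarial-sector labels for points/directions around the origin.

    Top cap (polar angle < 45 deg) is parietal (2); the remaining band splits
    by azimuth into frontal (1, around +y), occipital (3, around -y) and
    temporal (4, around both +-x).
    """
    p = np.asarray(points, float)
    r = np.linalg.norm(p, axis=1)
    r = np.where(r == 0, 1.0, r)
    polar = np.degrees(np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0)))
    az = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    labels = np.full(len(p), 4, dtype=np.int32)
    labels[(az > FRONTAL_AZ_DEG[0]) & (az < FRONTAL_AZ_DEG[1])] = 1
    labels[(az > OCCIPITAL_AZ_DEG[0]) & (az < OCCIPITAL_AZ_DEG[1])] = 3
    labels[polar < PARIETAL_POLAR_DEG] = 2
    return labels


def sector_boundary_margin_mm(points: np.ndarray) -> np.ndarray:
    """Approximate distance (mm) from each point to the nearest sector boundary."""
    p = np.asarray(points, float)
    r = np.linalg.norm(p, axis=1)
    safe_r = np.where(r == 0, 1.0, r)
    polar = np.degrees(np.arccos(np.clip(p[:, 2] / safe_r, -1.0, 1.0)))
    az = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    cap_margin = np.abs(polar - PARIETAL_POLAR_DEG)
    az_bounds = np.array([*FRONTAL_AZ_DEG, *OCCIPITAL_AZ_DEG])
    daz = np.min(np.abs(az[:, None] - az_bounds[None, :]), axis=1)
    az_margin = daz * np.sin(np.radians(polar))
    in_cap = polar < PARIETAL_POLAR_DEG
    margin_deg = np.where(in_cap, cap_margin, np.minimum(cap_margin, az_margin))
    return np.radians(margin_deg) * r


def sector_gap_field(gaps_mm: dict[int, float]):
    """Gap field assigning a region-specific constant gap by sector label."""
    def field_fn(dirs: np.ndarray) -> np.ndarray:
        labels = sector_labels(dirs)
        out = np.empty(len(labels), float)
        for lab, g in gaps_mm.items():
            out[labels == lab] = g
        return out
    return field_fn


def sector_atlas(extent_mm: float, voxel_size_mm: float = 2.0) -> RegionAtlas:
    """Label volume whose every voxel carries the sector label of its centre."""
    n = int(np.ceil(2 * extent_mm / voxel_size_mm)) + 1
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -extent_mm
    idx = np.indices((n, n, n)).reshape(3, -1).T
    world = idx * voxel_size_mm - extent_mm
    grid = sector_labels(world).reshape(n, n, n)
    return RegionAtlas(label_grid=grid, affine=affine)


# --------------------------------------------------------------------------
# longitudinal cohorts
# --------------------------------------------------------------------------

@dataclass
class ArmSpec:
    """One enrolment arm: a group sampled over one entry-age window."""

    group: str
    n_subjects: int
    sex_ratio_male: float
    entry_age_range: tuple[float, float]
    n_scans: int
    scan_interval_years: float
    icv_intercept: dict          # {"mean", "sd", "male_offset"} in mL
    thickness_intercept: dict    # {"mean", "sd", "male_offset"} in mm
    d_icv: dict                  # stratum -> (mean, sd) mL/year
    d_thickness: dict            # stratum -> (mean, sd) mm/year
    icv_noise_sd: float = 7.0
    thickness_noise_sd: float = 0.05
    coupling: str = "independent"            # or "inward_remodeling"
    remodeling_gain_ml_per_mm: float = 0.0   # mL lost per mm gained

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ParameterError("scans per subject must be >= 1")
        if self.icv_noise_sd < 0 or self.thickness_noise_sd < 0:
            raise ParameterError("noise sds must be >= 0")
        if self.coupling not in ("independent", "inward_remodeling"):
            raise ParameterError(f"unknown coupling mode {self.coupling!r}")


@dataclass
class CohortSpec:
    arms: list[ArmSpec]
    seed: int = 0
    age_split: float = 20.0

    @classmethod
    def from_dict(cls, payload: dict, seed: int | None = None) -> "CohortSpec":
        arms = [ArmSpec(**{**arm, "entry_age_range": tuple(arm["entry_age_range"])})
                for arm in payload["arms"]]
        return cls(arms=arms, seed=payload.get("seed", 0) if seed is None else seed,
                   age_split=payload.get("age_split", 20.0))

    @classmethod
    def from_json(cls, path: str | Path, seed: int | None = None) -> "CohortSpec":
        return cls.from_dict(json.loads(Path(path).read_text()), seed=seed)


def load_default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The shipped three-group template (MLD / MS / control, two age strata)."""
    payload = json.loads(
        resources.files("cranioquant").joinpath("data/cohort_default.json").read_text()
    )
    return CohortSpec.from_dict(payload, seed=seed)


def _piecewise_value(age, entry, intercept, slope_u20, slope_o20, split):
    """Latent trajectory: linear within each stratum, continuous at the split."""
    years_under = max(min(age, split) - min(entry, split), 0.0)
    years_over = max(max(age, split) - max(entry, split), 0.0)
    return intercept + slope_u20 * years_under + slope_o20 * years_over


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a longitudinal scan table from the cohort specification.

    Per subject: sex, entry age, ICV/thickness intercepts and per-stratum
    slopes are drawn; per scan, the latent piecewise-linear trajectory is
    evaluated and measurement noise added. In ``inward_remodeling`` mode the
    latent ICV slope is exactly ``-gain * thickness slope`` (no independent
    ICV-slope draw), so thickness gain and ICV loss are coupled before noise.
    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for arm_idx, arm in enumerate(spec.arms):
        for i in range(arm.n_subjects):
            sid = f"{arm.group}_{arm_idx}_{i:03d}"
            male = rng.random() < arm.sex_ratio_male
            entry = rng.uniform(*arm.entry_age_range)
            icv0 = rng.normal(arm.icv_intercept["mean"], arm.icv_intercept["sd"]) + (
                arm.icv_intercept.get("male_offset", 0.0) if male else 0.0
            )
            thk0 = rng.normal(arm.thickness_intercept["mean"], arm.thickness_intercept["sd"]) + (
                arm.thickness_intercept.get("male_offset", 0.0) if male else 0.0
            )
            s_thk = {
                stratum: rng.normal(*arm.d_thickness.get(stratum, (0.0, 0.0)))
                for stratum in ("under20", "over20")
            }
            if arm.coupling == "inward_remodeling":
                s_icv = {k: -arm.remodeling_gain_ml_per_mm * v for k, v in s_thk.items()}
            else:
                s_icv = {
                    stratum: rng.normal(*arm.d_icv.get(stratum, (0.0, 0.0)))
                    for stratum in ("under20", "over20")
                }
            for j in range(arm.n_scans):
                age = entry + j * arm.scan_interval_years
                icv = _piecewise_value(age, entry, icv0, s_icv["under20"], s_icv["over20"], spec.age_split)
                thk = _piecewise_value(age, entry, thk0, s_thk["under20"], s_thk["over20"], spec.age_split)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": arm.group,
                        "sex": "male" if male else "female",
                        "age_years": age,
                        "icv_ml": icv + rng.normal(0.0, arm.icv_noise_sd),
                        "thickness_mm": thk + rng.normal(0.0, arm.thickness_noise_sd),
                        "scanner_id": "sim",
                    }
                )
    return pd.DataFrame(rows)


def generate_association_cohort(
    n_subjects: int = 100,
    n_scans: int = 3,
    beta_thickness_ml_per_mm: float = -15.0,
    beta_sex_ml: float = 120.0,
    intercept_ml: float = 1500.0,
    random_intercept_sd_ml: float = 80.0,
    residual_sd_ml: float = 20.0,
    thickness_mean_mm: float = 6.5,
    thickness_sd_mm: float = 0.9,
    thickness_slope_mm_per_year: tuple[float, float] = (0.15, 0.10),
    seed: int = 0,
) -> pd.DataFrame:
    """Adult cohort drawn directly from the random-intercept association model.

    icv_ij = intercept + beta_thickness * thickness_ij + beta_sex * male_i
             + a_i + e_ij,   a_i ~ N(0, ri_sd^2),  e_ij ~ N(0, resid_sd^2),

    with per-subject thickness trajectories (baseline + linear drift) giving
    the within-subject variation that identifies beta. Ground truth for
    mixed-model parameter recovery.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        male = rng.random() < 0.5
        a_i = rng.normal(0.0, random_intercept_sd_ml)
        thk0 = rng.normal(thickness_mean_mm, thickness_sd_mm)
        s_thk = rng.normal(*thickness_slope_mm_per_year)
        entry = rng.uniform(25.0, 55.0)
        for j in range(n_scans):
            age = entry + 2.0 * j
            thk = thk0 + s_thk * (age - entry)
            icv = (
                intercept_ml
                + beta_thickness_ml_per_mm * thk
                + (beta_sex_ml if male else 0.0)
                + a_i
                + rng.normal(0.0, residual_sd_ml)
            )
            rows.append(
                {
                    "subject_id": f"assoc_{i:03d}",
                    "group": "sim",
                    "sex": "male" if male else "female",
                    "age_years": age,
                    "icv_ml": icv,
                    "thickness_mm": thk,
                    "scanner_id": "sim",
                }
            )
    return pd.DataFrame(rows)


def generate_mesh_cohort(
    n_subjects: int = 5,
    n_scans: int = 3,
    scan_interval_years: float = 5.0,
    remodeling_rate_mm_per_year: tuple[float, float] = (0.15, 0.0),
    entry_age_range: tuple[float, float] = (25.0, 45.0),
    inner_radius_range_mm: tuple[float, float] = (72.0, 85.0),
    base_gap_range_mm: tuple[float, float] = (4.0, 7.0),
    subdivision: int = 3,
    seed: int = 0,
) -> tuple[list[dict], pd.DataFrame]:
    """Small end-to-end cohort of evolving mesh phantoms with a truth table.

    Each subject is a sphere phantom whose inner table recedes at the
    subject's remodeling rate; every scan yields an (inner, outer) mesh pair
    plus the true ICV and thickness. Meshes are heavy, so keep n small.
    Returns ``(scan_records, truth_table)`` where each scan record carries
    subject_id, age_years and the phantom for that scan.
    """
    rng = np.random.default_rng(seed)
    scans: list[dict] = []
    truth_rows = []
    for i in range(n_subjects):
        sid = f"phantom_{i:03d}"
        radius = rng.uniform(*inner_radius_range_mm)
        gap = rng.uniform(*base_gap_range_mm)
        entry = rng.uniform(*entry_age_range)
        rate = max(0.0, rng.normal(*remodeling_rate_mm_per_year))
        base = make_shell_phantom("sphere", radius, gap, subdivision=subdivision, seed=int(rng.integers(2**31)))
        for j in range(n_scans):
            age = entry + j * scan_interval_years
            offset = rate * (age - entry)
            ph = base if offset == 0 else evolve_inward(base, offset, 1)[0]
            scans.append({"subject_id": sid, "age_years": age, "phantom": ph})
            truth_rows.append(
                {
                    "subject_id": sid,
                    "age_years": age,
                    "true_icv_ml": ph.true_icv_ml,
                    "true_thickness_mm": gap + offset,
                    "remodeling_rate_mm_per_year": rate,
                }
            )
    return scans, pd.DataFrame(truth_rows)


def measure_mesh_cohort(
    scans: list[dict], n_points: int = 50_000, k: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Run the thickness/volume pipeline over a mesh cohort -> scan table."""
    rows = []
    for idx, scan in enumerate(scans):
        ph = scan["phantom"]
        _, summary = measure_skull(
            ph.inner_mesh, ph.outer_mesh, n_points=n_points, k=k, seed=seed + idx
        )
        rows.append(
            {
                "subject_id": scan["subject_id"],
                "group": "phantom",
                "sex": "female",
                "age_years": scan["age_years"],
                "icv_ml": enclosed_volume(ph.inner_mesh),
                "thickness_mm": summary.median_mm,
                "scanner_id": "phantom",
            }
        )
    return pd.DataFrame(rows)
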