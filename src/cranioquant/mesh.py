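"""Triangle-mesh primitives: I/O, area-uniform surface sampling, enclosed volume.

All coordinates are in millimetres (world space); enclosed volumes are
reported in millilitres (mm^3 / 1000). Meshes are plain vertex/face arrays —
`trimesh` is used for file parsing and icosphere construction, while the
numerical operations (sampling, signed volume) are implemented here so their
conventions are explicit and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    DegenerateGeometryError,
    MeshFormatError,
    TopologyError,
)

logger = logging.getLogger(__name__)

_SUPPORTED_FORMATS = ("ply", "stl", "off")

MM3_PER_ML = 1000.0


@dataclass
class TriangleMesh:
    """A triangle surface in mm world coordinates.

    Faces are counter-clockwise when viewed from outside, so that a closed,
    consistently oriented surface encloses a positive signed volume.
    """

    vertices: np.ndarray  # (V, 3) float64, mm
    faces: np.ndarray     # (F, 3) int
    watertight: bool = field(default=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (F, 3) array of vertex triples")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshFormatError("face index exceeds vertex count")
        self.watertight = _is_watertight(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        """Per-face triangle area in mm^2."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())


@dataclass
class SurfacePointCloud:
    """Points sampled on a mesh surface, with provenance."""

    points: np.ndarray       # (N, 3) mm
    source_face: np.ndarray  # (N,) int face indices
    seed: int

    def __len__(self) -> int:
        return len(self.points)


def _is_watertight(faces: np.ndarray) -> bool:
    """Closed 2-manifold test: every undirected edge shared by exactly 2 faces."""
    if len(faces) == 0:
        return False
    edges = _undirected_edges(faces)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _undirected_edges(faces: np.ndarray) -> np.ndarray:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(edges, axis=1)


def boundary_edge_count(mesh: TriangleMesh) -> int:
    """Number of undirected edges not shared by exactly two faces."""
    edges = _undirected_edges(mesh.faces)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def read_mesh(path: str | Path, file_format: str | None = None) -> TriangleMesh:
    """Load a PLY, STL or OFF surface into a :class:`TriangleMesh`.

    Parameters
    ----------
    path
        Mesh file. Coordinates are interpreted as millimetres.
    file_format
        Force a format; inferred from the extension when omitted.

    Degenerate (zero-area) faces are retained — they carry no sampling
    probability but matter for topology — with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {_SUPPORTED_FORMATS}")
    try:
        loaded = trimesh.load(path, file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - propagate as I/O failure
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    if fmt == "stl":
        # STL is a triangle soup: merge bit-identical duplicate vertices so
        # closed surfaces come back watertight
        loaded.merge_vertices()
    faces = np.asarray(loaded.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        bad = next((i for i, f in enumerate(loaded.faces) if len(f) != 3), -1)
        raise MeshFormatError(f"non-triangular face at index {bad} in {path}")
    mesh = TriangleMesh(np.asarray(loaded.vertices, dtype=np.float64), faces)
    n_degenerate = int(np.sum(mesh.face_areas() == 0.0))
    if n_degenerate:
        logger.warning("%s: %d zero-area face(s) retained", path.name, n_degenerate)
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path, file_format: str | None = None) -> Path:
    """Write a mesh as ascii PLY/OFF or binary STL, re-readable by :func:`read_mesh`."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    try:
        if fmt == "ply":
            data = tm.export(file_type="ply", encoding="ascii")
        else:
            data = tm.export(file_type=fmt)
        if isinstance(data, str):
            data = data.encode()
        path.write_bytes(data)
    except OSError as exc:
        raise IOError(f"cannot write mesh to {path}: {exc}") from exc
    return path


def sample_surface(mesh: TriangleMesh, n: int, seed: int) -> SurfacePointCloud:
    """Area-weighted uniform sampling of ``n`` points on the mesh surface.

    A face is chosen by inverse-CDF lookup on the cumulative face area with a
    single uniform draw per point, then a position is placed uniformly inside
    the triangle via the reflected-barycentric construction. Identical
    ``(mesh, n, seed)`` always yields an identical cloud. Zero-area faces get
    zero probability but stay in the mesh.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0.0:
        raise DegenerateGeometryError("all faces have zero area; nothing to sample")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(areas)
    cdf /= cdf[-1]
    face_idx = np.searchsorted(cdf, rng.random(n), side="right")
    face_idx = np.minimum(face_idx, len(areas) - 1)

    # uniform barycentric placement: fold (u, v) back into the lower triangle
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1.0
    u[flip] = 1.0 - u[flip]
    v[flip] = 1.0 - v[flip]

    tri = mesh.vertices[mesh.faces[face_idx]]
    points = tri[:, 0] + u[:, None] * (tri[:, 1] - tri[:, 0]) + v[:, None] * (tri[:, 2] - tri[:, 0])
    return SurfacePointCloud(points=points, source_face=face_idx, seed=seed)


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume (mL) enclosed by a watertight, consistently oriented mesh.

    Sum of signed tetrahedron volumes (origin, v0, v1, v2) over all faces —
    the divergence theorem on a closed surface — so the result is invariant
    under rigid translation. A negative total indicates inward winding; the
    orientation is flipped automatically with a logged notice.
    """
    if not mesh.watertight:
        raise TopologyError(
            f"mesh is not watertight ({boundary_edge_count(mesh)} boundary/non-manifold edges); "
            "enclosed volume is undefined"
        )
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])) / 6.0
    total_mm3 = float(signed.sum())
    if total_mm3 < 0:
        logger.info("mesh wound inward (signed volume %.3f mm^3); flipping orientation", total_mm3)
        total_mm3 = -total_mm3
    return total_mm3 / MM3_PER_ML
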