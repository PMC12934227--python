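import numpy as np
import pytest

from cranioquant import TriangleMesh, make_shell_phantom


@pytest.fixture(scope="session")
def tetrahedron() -> TriangleMesh:
    """Smallest closed triangle mesh, outward-oriented."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(vertices, faces)


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    """Axis-aligned 1 mm cube (12 outward-oriented triangles)."""
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


@pytest.fixture(scope="session")
def sphere_phantom():
    """Concentric-sphere skull phantom: inner R = 80 mm, uniform 3 mm gap."""
    return make_shell_phantom("sphere", 80.0, 3.0, subdivision=4, seed=0)


def brute_force_knn_mean(outer: np.ndarray, inner: np.ndarray, k: int) -> np.ndarray:
    """Independent O(N*M) oracle: full pairwise distances, sort, mean of k smallest."""
    diff = outer[:, None, :] - inner[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=2))
    dists.sort(axis=1)
    return dists[:, :k].mean(axis=1)
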