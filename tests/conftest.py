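import logging

import numpy as np
import pytest
import trimesh

from condylefit.anatomy import AnatomicalFrame, LandmarkSet, detect_landmarks
from condylefit.synthetic import generate_condyle_mesh

logging.getLogger("condylefit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fine_fixture():
    """Synthetic bicondylar mesh at 3 mm edges with analytic landmarks."""
    return generate_condyle_mesh(edge_length=3.0)


@pytest.fixture(scope="session")
def coarse_fixture():
    """Synthetic bicondylar mesh at 8 mm edges with analytic landmarks."""
    return generate_condyle_mesh(edge_length=8.0)


@pytest.fixture(scope="session")
def fine_landmarks(fine_fixture):
    mesh, analytic = fine_fixture
    return detect_landmarks(mesh, analytic.frame, mesh.metadata["face_region"])


@pytest.fixture(scope="session")
def coarse_landmarks(coarse_fixture):
    mesh, analytic = coarse_fixture
    return detect_landmarks(mesh, analytic.frame, mesh.metadata["face_region"])


@pytest.fixture
def canonical_frame():
    return AnatomicalFrame(
        origin=np.zeros(3),
        coronal_axis=np.array([1.0, 0.0, 0.0]),
        sagittal_axis=np.array([0.0, 1.0, 0.0]),
        vertical_axis=np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture
def simple_landmarks(canonical_frame):
    """Hand-placed landmark set: medial span 30 mm, lateral span 20 mm."""
    return LandmarkSet(
        M_medial=np.array([0.0, 0.0, 0.0]),
        M_lateral=np.array([30.0, 0.0, 0.0]),
        M_high=np.array([15.0, 0.0, 18.0]),
        M_low=np.array([15.0, 0.0, -18.0]),
        L_medial=np.array([50.0, 0.0, 0.0]),
        L_lateral=np.array([70.0, 0.0, 0.0]),
        L_high=np.array([60.0, 0.0, 16.0]),
        L_low=np.array([60.0, 0.0, -16.0]),
        frame=canonical_frame,
    )


def make_grid_mesh(n: int = 20, pitch: float = 1.0, z: float = 0.0) -> trimesh.Trimesh:
    """Flat triangulated n x n grid in the z-plane."""
    xs = np.arange(n + 1) * pitch
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
    vid = np.arange((n + 1) * (n + 1)).reshape(n + 1, n + 1)
    faces = []
    for i in range(n):
        for j in range(n):
            a, b, c, d = vid[i, j], vid[i + 1, j], vid[i + 1, j + 1], vid[i, j + 1]
            faces.extend([[a, b, c], [a, c, d]])
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
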