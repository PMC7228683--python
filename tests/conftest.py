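"""Shared fixtures: tiny canonical meshes and cached synthetic torsos."""

import numpy as np
import pytest

from ibccontour.mesh_io import TriangleMesh
from ibccontour.pipeline import detect
from ibccontour.synthetic import TorsoParams, generate_torso


def tetrahedron(scale: float = 100.0) -> TriangleMesh:
    """Smallest closed mesh, outward winding, edge ~scale mm."""
    v = scale * np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(vertices=v, faces=f, provenance="tetra")


def flat_disk(radius: float = 50.0, edge: float = 5.0) -> TriangleMesh:
    """Triangulated disk in the z=0 plane, normals +z; one boundary loop."""
    n = int(2 * radius / edge) + 1
    g = np.linspace(-radius, radius, n)
    X, Y = np.meshgrid(g, g, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00, v10 = i * n + j, (i + 1) * n + j
            v01, v11 = i * n + j + 1, (i + 1) * n + j + 1
            faces += [[v00, v10, v11], [v00, v11, v01]]
    faces = np.asarray(faces)
    keep = (np.linalg.norm(verts[faces].mean(axis=1)[:, :2], axis=1) < radius)
    faces = faces[keep]
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices=verts[used], faces=remap[faces], provenance="disk")


def mirror_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """x -> -x with faces rewound, preserving vertex order and outwardness."""
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    return TriangleMesh(vertices=v, faces=mesh.faces[:, ::-1].copy(),
                        provenance=mesh.provenance + "|mirror")


@pytest.fixture(scope="session")
def tetra():
    return tetrahedron()


@pytest.fixture(scope="session")
def disk():
    return flat_disk()


@pytest.fixture(scope="session")
def coarse_case():
    """Grade-2 torso at reduced resolution for fast unit tests."""
    return generate_torso(TorsoParams(grade=2, seed=1, edge_length=3.0,
                                      noise_mm=0.3))


@pytest.fixture(scope="session")
def coarse_case_g0():
    return generate_torso(TorsoParams(grade=0, seed=1, edge_length=3.0,
                                      noise_mm=0.3))


@pytest.fixture(scope="session")
def default_case():
    """Grade-2 torso at the study conditions (1.5 mm edge, 0.3 mm noise)."""
    return generate_torso(TorsoParams(grade=2, seed=1))


@pytest.fixture(scope="session")
def default_detection(default_case):
    return detect(default_case.mesh)
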