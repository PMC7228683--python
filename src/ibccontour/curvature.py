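"""Per-vertex principal curvatures, one-ring normals, and shape index.

Principal curvatures are estimated with the normal-cycle (tensor-averaging)
estimator: for each vertex the curvature tensor is integrated over the edges
of its one-ring,

    T(v) = (1/A_v) * sum_{e ∋ v}  beta(e) * (|e| / 2) * ê êᵀ ,

where ``beta(e)`` is the signed dihedral angle at edge ``e`` (positive at
convex edges under the outward-normal convention), ``ê`` the unit edge
direction, ``|e|/2`` the length of the edge inside the barycentric cell of
``v`` and ``A_v`` the barycentric cell area (one third of the incident face
area).  The eigenvector of ``T`` closest to the vertex normal is discarded;
the remaining two eigenvalues estimate the principal curvatures (the tensor
associates each eigenvalue with the *orthogonal* principal direction, which
leaves the value pair unchanged).  Convex regions, bulging along the outward
normal, have positive curvatures.

The shape index is the scale-free surface-type descriptor

    S = (2/pi) * atan( (kmax + kmin) / (kmax - kmin) )  in [-1, 1],

positive on convex mounds, negative in concave creases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CurvatureError
from .mesh_io import TriangleMesh

log = logging.getLogger(__name__)

__all__ = ["CurvatureField", "principal_curvatures", "vertex_normals", "shape_index"]

#: below this spread (1/mm) the two principal curvatures are considered equal
DEGENERATE_EPS = 1e-9


@dataclass
class CurvatureField:
    """Per-vertex curvature data aligned with ``mesh.vertices``."""

    mesh: TriangleMesh
    kmax: np.ndarray  # (n,) 1/mm
    kmin: np.ndarray  # (n,) 1/mm
    normal: np.ndarray  # (n, 3) unit
    is_boundary: np.ndarray  # (n,) bool -- vertex on an open boundary edge
    S: np.ndarray | None = None  # shape index, filled by shape_index()


def _face_geometry(mesh: TriangleMesh):
    a, b, c = (mesh.vertices[mesh.faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1)
    if np.any(norm == 0):
        raise CurvatureError("mesh contains zero-area faces")
    return n / norm[:, None], norm / 2.0  # unit normals, areas


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """One-ring vertex normals: sum of unit normals of incident faces.

    Falls back to the area-weighted average at vertices where the plain sum
    cancels (pathological folds); raises if that is zero too.
    """
    fn, areas = _face_geometry(mesh)
    n = np.zeros((mesh.n_vertices, 3))
    nw = np.zeros((mesh.n_vertices, 3))
    for i in range(3):
        np.add.at(n, mesh.faces[:, i], fn)
        np.add.at(nw, mesh.faces[:, i], fn * areas[:, None])
    length = np.linalg.norm(n, axis=1)
    bad = length < 1e-12
    counts = np.zeros(mesh.n_vertices, dtype=int)
    np.add.at(counts, mesh.faces.ravel(), 1)
    bad &= counts > 0
    if np.any(bad):
        wlen = np.linalg.norm(nw[bad], axis=1)
        if np.any(wlen < 1e-12):
            raise CurvatureError(
                f"degenerate normal at vertices {np.nonzero(bad)[0][wlen < 1e-12][:5]}"
            )
        n[bad] = nw[bad]
        length = np.linalg.norm(n, axis=1)
    length[length == 0] = 1.0  # isolated vertices keep a zero normal
    return n / length[:, None]


def _edge_structure(mesh: TriangleMesh):
    """Unique undirected edges with incident-face pairs and orientation."""
    m = mesh.n_faces
    directed = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    face_of = np.tile(np.arange(m), 3)
    order = np.array(directed[:, 0] < directed[:, 1])  # True if stored as (a<b)
    undirected = np.sort(directed, axis=1)
    edges, inverse = np.unique(undirected, axis=0, return_inverse=True)
    ne = len(edges)
    face_fwd = np.full(ne, -1, dtype=np.int64)  # face traversing a->b (a<b)
    face_bwd = np.full(ne, -1, dtype=np.int64)  # face traversing b->a
    fwd = order
    face_fwd[inverse[fwd]] = face_of[fwd]
    face_bwd[inverse[~fwd]] = face_of[~fwd]
    return edges, face_fwd, face_bwd


def principal_curvatures(mesh: TriangleMesh) -> CurvatureField:
    """Estimate per-vertex principal curvatures (normal-cycle, one-ring)."""
    if mesh.n_vertices < 4:
        raise CurvatureError("mesh has fewer than 4 vertices")
    fn, areas = _face_geometry(mesh)
    edges, face_fwd, face_bwd = _edge_structure(mesh)
    interior = (face_fwd >= 0) & (face_bwd >= 0)

    va = mesh.vertices[edges[:, 0]]
    vb = mesh.vertices[edges[:, 1]]
    evec = vb - va
    elen = np.linalg.norm(evec, axis=1)
    ehat = evec / elen[:, None]

    beta = np.zeros(len(edges))
    n1 = fn[face_fwd[interior]]
    n2 = fn[face_bwd[interior]]
    e_int = ehat[interior]
    # signed dihedral angle; orientation chosen so convex edges are positive
    sin_b = np.einsum("ij,ij->i", np.cross(n1, n2), e_int)
    cos_b = np.clip(np.einsum("ij,ij->i", n1, n2), -1.0, 1.0)
    beta[interior] = np.arctan2(sin_b, cos_b)

    # accumulate the 3x3 tensor at both endpoints of every edge
    weight = beta * elen / 2.0
    outer = ehat[:, :, None] * ehat[:, None, :]  # (ne, 3, 3)
    contrib = weight[:, None, None] * outer
    T = np.zeros((mesh.n_vertices, 3, 3))
    np.add.at(T, edges[:, 0], contrib)
    np.add.at(T, edges[:, 1], contrib)

    cell_area = np.zeros(mesh.n_vertices)
    for i in range(3):
        np.add.at(cell_area, mesh.faces[:, i], areas / 3.0)
    isolated = cell_area == 0
    if np.any(isolated):
        warnings.warn(
            f"{int(isolated.sum())} isolated vertices: curvatures set to 0",
            stacklevel=2,
        )
        cell_area[isolated] = 1.0
    T /= cell_area[:, None, None]

    evals, evecs = np.linalg.eigh(T)  # ascending eigenvalues
    normals = vertex_normals(mesh)
    # discard the eigenvector most aligned with the vertex normal
    align = np.abs(np.einsum("nij,ni->nj", evecs, normals))  # (n, 3)
    drop = np.argmax(align, axis=1)
    idx = np.arange(mesh.n_vertices)
    keep = np.ones((mesh.n_vertices, 3), dtype=bool)
    keep[idx, drop] = False
    kept = evals[keep].reshape(mesh.n_vertices, 2)
    kmin = kept.min(axis=1)
    kmax = kept.max(axis=1)
    kmin[isolated] = 0.0
    kmax[isolated] = 0.0

    # boundary vertices: curvature comes from a truncated ring; flag them so
    # downstream statistics (kmean) can exclude the artificial ROI rim
    bedge = edges[(face_fwd < 0) | (face_bwd < 0)]
    is_boundary = np.zeros(mesh.n_vertices, dtype=bool)
    is_boundary[bedge.ravel()] = True

    return CurvatureField(
        mesh=mesh,
        kmax=kmax,
        kmin=kmin,
        normal=normals,
        is_boundary=is_boundary,
    )


def shape_index(field: CurvatureField) -> CurvatureField:
    """Populate the shape index S in-place (and return the field).

    Degenerate vertices (|kmax - kmin| below 1e-9/mm) take the continuous
    limit: S = sign(kmax + kmin), and S = 0 if the sum also vanishes.
    """
    ksum = field.kmax + field.kmin
    kdiff = field.kmax - field.kmin
    S = np.zeros_like(ksum)
    ok = np.abs(kdiff) >= DEGENERATE_EPS
    S[ok] = (2.0 / np.pi) * np.arctan(ksum[ok] / kdiff[ok])
    umbilic = ~ok & (np.abs(ksum) >= DEGENERATE_EPS)
    S[umbilic] = np.sign(ksum[umbilic])
    field.S = S
    return field


def save_scalar_ply(mesh: TriangleMesh, scalar: np.ndarray, path, name="quality"):
    """Write an ascii PLY with one extra per-vertex float property.

    Lets external viewers pseudo-colour S or kmin over the surface.
    """
    scalar = np.asarray(scalar, dtype=float)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        f"property float {name}",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, s in zip(mesh.vertices, scalar):
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {s:.6g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
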