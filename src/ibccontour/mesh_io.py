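"""Triangle-mesh and contour-annotation I/O.

Coordinate convention (used by every downstream stage)
------------------------------------------------------
All coordinates are in millimetres.  ``+y`` is superior (up), ``+z`` is
anterior (toward the camera), ``+x`` is the subject's anatomical left /
viewer's right.  "Lowest", "downward" and "above" throughout the package are
defined against this frame; in particular the lowest visible point is the
minimum-``y`` point of the breast overhang.

Meshes whose bounding-box diagonal is smaller than 10 (i.e. plausibly in
metres) are rescaled to millimetres with a warning.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshFormatError, RoiError

log = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "RoiBox",
    "ContourAnnotation",
    "BoundaryLoop",
    "load_mesh",
    "save_mesh",
    "crop_roi",
    "detect_holes",
    "read_annotation",
    "write_annotation",
]


@dataclass
class TriangleMesh:
    """A validated triangle surface mesh, vertices in mm.

    Face winding is globally consistent and oriented outward from the body
    (anterior normals have positive mean z-component).
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64
    provenance: str = "unknown"

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] coordinate bounds."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        """Per-face normals ``(b-a) x (c-a)`` following the winding."""
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.provenance)


@dataclass
class RoiBox:
    """Axis-aligned crop box in mm (stands in for a manual ROI crop)."""

    min_corner: np.ndarray  # (3,)
    max_corner: np.ndarray  # (3,)

    def __post_init__(self):
        self.min_corner = np.asarray(self.min_corner, dtype=float)
        self.max_corner = np.asarray(self.max_corner, dtype=float)
        if not np.all(self.min_corner < self.max_corner):
            raise ValueError("RoiBox requires min < max on every axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.all((points >= self.min_corner) & (points <= self.max_corner), axis=1)


@dataclass
class ContourAnnotation:
    """An ordered 3D polyline (mm), e.g. a manually traced contour."""

    points: np.ndarray  # (k, 3)
    label: str = "manual"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("annotation points must be (k, 3)")
        if len(self.points) < 4:
            raise MeshFormatError(
                f"annotation '{self.label}' has {len(self.points)} points; "
                "at least 4 are required for cubic-spline resampling"
            )
        dup = np.all(np.diff(self.points, axis=0) == 0, axis=1)
        if np.any(dup):
            raise MeshFormatError(
                f"annotation '{self.label}' has consecutive duplicate points "
                f"at rows {np.nonzero(dup)[0].tolist()}"
            )


@dataclass
class BoundaryLoop:
    """One open boundary of the mesh, as an ordered vertex loop."""

    vertex_indices: np.ndarray  # ordered loop
    centroid: np.ndarray = field(default=None)
    extent: np.ndarray = field(default=None)  # bbox size of the loop

    def __len__(self):
        return len(self.vertex_indices)


# ---------------------------------------------------------------------------
# validation


def _unique_edges(faces: np.ndarray):
    """Undirected unique edges, their multiplicity, and the directed set."""
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    undirected = np.sort(directed, axis=1)
    edges, inverse, counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    return edges, inverse, counts, directed


def _winding_consistent(faces: np.ndarray) -> bool:
    """Each interior edge must appear once in each direction."""
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    # an edge traversed twice in the same direction betrays a flipped face
    _, counts = np.unique(directed, axis=0, return_counts=True)
    return bool(np.all(counts == 1))


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip all faces if the mesh is inside-out under our convention."""
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if tm.is_watertight:
        if tm.volume < 0:
            return faces[:, ::-1]
        return faces
    # open patch: anterior-half mean normal must point toward +z
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)  # area-weighted
    zc = (a[:, 2] + b[:, 2] + c[:, 2]) / 3.0
    anterior = zc >= np.median(zc)
    if n[anterior, 2].sum() < 0:
        return faces[:, ::-1]
    return faces


def _validate(vertices: np.ndarray, faces: np.ndarray, provenance: str) -> TriangleMesh:
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise MeshFormatError(f"{provenance}: empty mesh")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshFormatError(f"{provenance}: faces are not triangles")
    if not np.all(np.isfinite(vertices)):
        raise MeshFormatError(f"{provenance}: non-finite vertex coordinates")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise MeshFormatError(f"{provenance}: face index out of range")

    diag = np.linalg.norm(vertices.max(axis=0) - vertices.min(axis=0))
    if diag < 10.0:
        warnings.warn(
            f"{provenance}: bounding-box diagonal {diag:.3g} < 10; "
            "assuming metres and rescaling to millimetres",
            stacklevel=2,
        )
        vertices = vertices * 1000.0

    # drop degenerate (zero-area) faces
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    keep = area2 > 0
    if not np.all(keep):
        log.info("%s: dropping %d zero-area faces", provenance, int((~keep).sum()))
        faces = faces[keep]
        if len(faces) == 0:
            raise MeshFormatError(f"{provenance}: all faces degenerate")

    if not _winding_consistent(faces):
        log.warning("%s: inconsistent face winding; reorienting", provenance)
        tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        trimesh.repair.fix_normals(tm)
        faces = np.asarray(tm.faces, dtype=np.int64)

    faces = _orient_outward(vertices, faces)
    mesh = TriangleMesh(vertices=vertices, faces=faces, provenance=provenance)
    log.info(
        "%s: %d vertices, %d faces", provenance, mesh.n_vertices, mesh.n_faces
    )
    return mesh


# ---------------------------------------------------------------------------
# file formats


def _scan_obj_for_polygons(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("f "):
            if len(line.split()) - 1 > 3:
                raise MeshFormatError(
                    f"OBJ line {lineno}: non-triangular face '{line.strip()}'"
                )


def _scan_ascii_ply_for_polygons(text: str) -> None:
    lines = text.splitlines()
    n_vert = n_face = 0
    header_end = None
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:1] == ["end_header"]:
            header_end = i
            break
    if header_end is None:
        raise MeshFormatError("PLY: missing end_header")
    face_lines = lines[header_end + 1 + n_vert : header_end + 1 + n_vert + n_face]
    for k, line in enumerate(face_lines):
        parts = line.split()
        if parts and int(parts[0]) != 3:
            raise MeshFormatError(f"PLY face {k}: non-triangular ({parts[0]} vertices)")


def load_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Load and validate a PLY or OBJ triangle mesh.

    Parameters
    ----------
    path : str or Path
    fmt : {"auto", "ply", "obj"}
        "auto" infers the format from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")

    raw = path.read_bytes()
    if fmt == "obj":
        _scan_obj_for_polygons(raw.decode("utf-8", errors="replace"))
    elif fmt == "ply" and raw.startswith(b"ply") and b"format ascii" in raw[:256]:
        _scan_ascii_ply_for_polygons(raw.decode("utf-8", errors="replace"))

    try:
        tm = trimesh.load(io.BytesIO(raw), file_type=fmt, process=False)
    except Exception as exc:  # parser failure
        raise MeshFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: empty mesh")
        tm = geoms[0]
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path}: no triangle faces (empty mesh?)")
    if tm.faces.shape[0] and tm.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangular faces")
    return _validate(np.asarray(tm.vertices), np.asarray(tm.faces), str(path))


def save_mesh(mesh: TriangleMesh, path, fmt: str = "auto") -> None:
    """Write a mesh as ascii PLY or OBJ (inferred from extension)."""
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif fmt == "obj":
        data = tm.export(file_type="obj")
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)


# ---------------------------------------------------------------------------
# operations


def crop_roi(mesh: TriangleMesh, box: RoiBox) -> TriangleMesh:
    """Keep vertices inside the box and faces entirely inside; reindex."""
    inside = box.contains(mesh.vertices)
    if not np.any(inside):
        raise RoiError("ROI does not intersect mesh")
    face_ok = inside[mesh.faces].all(axis=1)
    if not np.any(face_ok):
        raise RoiError("ROI does not intersect mesh (no surviving faces)")
    faces = mesh.faces[face_ok]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(
        vertices=mesh.vertices[used],
        faces=remap[faces],
        provenance=f"{mesh.provenance}|roi",
    )


def detect_holes(mesh: TriangleMesh) -> list[BoundaryLoop]:
    """Return every open boundary as an ordered vertex loop.

    Boundary edges are edges with exactly one incident face.  An open patch
    always reports at least one loop (its outer rim); interior holes appear as
    additional loops.  Loops are sorted by descending vertex count, so for a
    patch with holes the first loop is (almost always) the outer rim.
    """
    edges, _, counts, _ = _unique_edges(mesh.faces)
    boundary = edges[counts == 1]
    if len(boundary) == 0:
        return []
    # walk loops: boundary vertices have (generically) degree 2
    neighbors: dict[int, list[int]] = {}
    for a, b in boundary:
        neighbors.setdefault(int(a), []).append(int(b))
        neighbors.setdefault(int(b), []).append(int(a))
    unvisited = {tuple(e) for e in np.sort(boundary, axis=1).tolist()}
    loops = []
    while unvisited:
        a0, b0 = min(unvisited)
        loop = [a0, b0]
        unvisited.discard((a0, b0))
        while True:
            prev, cur = loop[-2], loop[-1]
            nxt = None
            for cand in neighbors.get(cur, []):
                key = (min(cur, cand), max(cur, cand))
                if cand != prev and key in unvisited:
                    nxt = cand
                    unvisited.discard(key)
                    break
            if nxt is None:
                break
            if nxt == loop[0]:
                break
            loop.append(nxt)
        pts = mesh.vertices[loop]
        loops.append(
            BoundaryLoop(
                vertex_indices=np.asarray(loop, dtype=np.int64),
                centroid=pts.mean(axis=0),
                extent=pts.max(axis=0) - pts.min(axis=0),
            )
        )
    loops.sort(key=len, reverse=True)
    return loops


# ---------------------------------------------------------------------------
# contour annotations: plain text, one "x y z" per line, '#' comments


def read_annotation(path, label: str | None = None) -> ContourAnnotation:
    path = Path(path)
    pts = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise MeshFormatError(f"{path}:{lineno}: expected 'x y z', got {line!r}")
        pts.append([float(v) for v in parts])
    if not pts:
        raise MeshFormatError(f"{path}: no contour points")
    return ContourAnnotation(points=np.asarray(pts), label=label or path.stem)


def write_annotation(ann: ContourAnnotation, path) -> None:
    path = Path(path)
    lines = [f"# contour: {ann.label} ({len(ann.points)} points, mm)"]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in ann.points]
    path.write_text("\n".join(lines) + "\n")
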