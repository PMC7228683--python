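"""Parametric synthetic torsos with analytically known contour ground truth.

The generator emulates the cropped anterior torso of a 3D surface scan: a
gently convex chest-wall sheet ``z = base(x, y)`` carrying one compact-support
breast mound per side.  Design goals, in order:

1. the attachment crease of each mound (the inferior breast-chest contour)
   is a closed-form curve that the mesh resolves as a concave fold;
2. ptosis is controllable, with an overhang whose lowest downward-facing
   point (the lowest visible point) is known analytically;
3. the generator is deterministic under a seed, and symmetric parameter sets
   yield exactly x-mirror-symmetric cases.

Geometry
--------
Each mound is a radial bump of support radius ``rb`` around its centre
``(cx, cy)`` in the x-y plane.  The radial profile morphs with the polar
angle ``phi`` (measured from straight down):

* on the lower arc (|phi| <= 95 deg) the profile is ``(1-r^2)^{3/2}``, which
  meets the chest wall tangentially with bending concentrated at the support
  circle, plus a narrow groove (Gaussian indentation, depth 1.5 mm, sigma
  2 mm) centred exactly on the circle -- the sharp skin fold of a real
  inframammary crease, and the strongest concavity anywhere on the surface;
* toward the upper arc the profile blends into ``(1-r^2)^3``, whose second
  derivative vanishes at the rim: the mound merges smoothly into the chest
  and the crease fades out (real breasts have no fold above the mound).
  The blend envelope falls from 1 at 95 deg to 0 at 125 deg.

Ptosis is a shear of ambient space, ``y -> y - sag * w(z)``, where ``w``
ramps smoothly from 0 just below the fold level to 1 at the mound front:
the protruding tissue drops quasi-rigidly by ``sag`` millimetres while the
chest wall stays put.  The fold circle rides the shear (its warped image
stays closed form) and remains the strongest concave line on the surface;
the shear onset -- the "tuck" where the hanging mound turns toward the
chest -- is spread over the full mound depth so its curvature stays several
times weaker than the fold's.  For grade >= 1 the mound folds over into a
true overhang whose lowest point drops below every crease point, as in a
real ptotic breast where the fold hides under the hanging tissue.  A shear
of space is a bijection, so the warped mesh can never self-intersect.

The per-grade sag coefficients were fixed from the analytic mid-sagittal
profile so that the overhang bottom sits ~3 / 10 / 20 mm below the fold for
grades 1 / 2 / 3 (grade 0 has no shear and a maximum surface slope of ~49
degrees, leaving no downward-facing triangle within the 10-degree cone).

Noise emulates residual scanner surface error: a band-limited random field
(default wavelength 25 mm, the scale of multi-camera merge artifacts)
applied along vertex normals, scaled to the requested RMS amplitude.
Surface reconstruction smooths raw sensor noise away below the patch scale,
so the residual error of a scan mesh is spatially correlated; white noise of
the same amplitude would bury every anatomical curvature (its second
differences at 1.5 mm spacing exceed 0.5 /mm) and describes no real scanner.
The field is even in x so that symmetric cases stay exactly mirror-symmetric.

Ground truth is extracted from the closed-form surface, never from the
(noisy) mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .mesh_io import ContourAnnotation, TriangleMesh, save_mesh, write_annotation

__all__ = [
    "TorsoParams",
    "SyntheticCase",
    "generate_torso",
    "generate_analytic_surface",
    "write_case",
]

#: per-grade drop (mm) of the mound front under the ptosis shear
SAG_BY_GRADE = {0: 0.0, 1: 39.5, 2: 47.5, 3: 58.6}

#: blend envelope: crease fully sharp below this polar angle ...
ENVELOPE_FULL_DEG = 95.0
#: ... and completely smooth beyond this one
ENVELOPE_ZERO_DEG = 125.0

#: angular extent of the ground-truth crease annotation (degrees from the
#: lowest crease point; the fold stays curvature-dominant over this arc)
CREASE_GT_DEG = 120.0


@dataclass
class TorsoParams:
    """Generator parameters, all lengths in mm."""

    half_width: float = 160.0
    height: float = 300.0
    base_depth: float = 45.0
    base_halfspan: float = 180.0
    base_ybow: float = 6.0
    base_yspan: float = 230.0
    breast_offset_x: float = 72.0  # |x| of each breast centre
    breast_center_y: float = 165.0
    breast_radius: float = 60.0
    protrusion: float = 45.0
    grade: int = 0  # ptosis grade 0-3
    edge_length: float = 1.5
    noise_mm: float = 0.3  # RMS jitter along normals
    noise_wavelength: float = 25.0
    warp_z0: float = 40.0  # shear starts above this z level (mm)
    warp_ramp: float = 48.0  # shear saturates over this z span (mm)
    groove_depth: float = 1.5  # skin indentation along the fold (mm)
    groove_sigma: float = 2.0  # groove half-width (mm)
    hole: tuple[float, float, float] | None = None  # (x, y, radius)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in (
            "half_width",
            "height",
            "base_depth",
            "base_halfspan",
            "breast_radius",
            "protrusion",
            "edge_length",
            "noise_wavelength",
            "warp_ramp",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.grade not in (0, 1, 2, 3):
            problems.append("grade must be one of 0, 1, 2, 3")
        if self.edge_length > self.breast_radius / 5.0:
            problems.append(
                "edge_length must be <= breast_radius/5 so the crease is resolvable"
            )
        if self.noise_mm < 0:
            problems.append("noise_mm must be >= 0")
        elif self.noise_mm >= self.edge_length:
            problems.append("noise_mm must be < edge_length")
        if self.breast_offset_x + self.breast_radius > self.half_width:
            problems.append("breast does not fit inside the torso width")
        if not (
            self.breast_radius
            < self.breast_center_y
            < self.height - self.breast_radius
        ):
            problems.append("breast does not fit inside the torso height")
        if self.hole is not None and (len(self.hole) != 3 or self.hole[2] <= 0):
            problems.append("hole must be (x, y, radius>0)")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def sag(self) -> float:
        return SAG_BY_GRADE[self.grade]


@dataclass
class SyntheticCase:
    """A generated torso plus its analytic ground truth."""

    mesh: TriangleMesh
    crease: dict  # side -> ContourAnnotation (analytic attachment crease)
    lvp: dict  # side -> (3,) point or None (grade 0)
    params: TorsoParams = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# closed-form surface pieces


def _base_z(p: TorsoParams, x, y):
    """Chest-wall sheet: a gently convex elliptic-cylinder-like patch."""
    return p.base_depth * (1.0 - (x / p.base_halfspan) ** 2) + p.base_ybow * (
        1.0 - ((y - p.height / 2.0) / p.base_yspan) ** 2
    )


def _profile_fold(rho):
    """C1 compact bump with a concentrated concave fold at its rim.

    ``(1 - rho^2)^{3/2}`` decreases monotonically from a convex apex
    (f ~ 1 - 1.5 rho^2) and meets the chest wall tangentially, but with a
    second derivative that blows up at the rim: the bending is concentrated
    within 1-2 mesh edges of the support circle, like the sharp fold where a
    resting breast meets the chest wall.  At 1.5 mm resolution the resolved
    fold curvature is about -0.3 /mm, an order of magnitude stronger than
    any other concavity on the torso.
    """
    q = np.clip(1.0 - rho**2, 0.0, None)
    return q**1.5


def _profile_smooth(rho):
    """C2 compact bump: curvature-free rim, no crease."""
    q = np.clip(1.0 - rho**2, 0.0, None)
    return q**3


#: the rim amplitude of the upper blend fades to this fraction, over this
#: angular window, immediately after the crease envelope ends: the upper
#: pole of a breast projects little and shows no visible boundary
UPPER_AMPLITUDE_MIN = 0.10
UPPER_FADE_START_DEG = 98.0
UPPER_FADE_END_DEG = 125.0


def _upper_amplitude(phi_deg):
    """Rim-amplitude fade of the upper pole as a function of |angle|."""
    t = np.clip(
        (np.abs(phi_deg) - UPPER_FADE_START_DEG)
        / (UPPER_FADE_END_DEG - UPPER_FADE_START_DEG),
        0.0,
        1.0,
    )
    return 1.0 - (1.0 - UPPER_AMPLITUDE_MIN) * (3.0 * t**2 - 2.0 * t**3)


def _envelope(phi_deg):
    """Crease-sharpness envelope as a function of |polar angle|."""
    t = (np.abs(phi_deg) - ENVELOPE_FULL_DEG) / (ENVELOPE_ZERO_DEG - ENVELOPE_FULL_DEG)
    t = np.clip(t, 0.0, 1.0)
    return 1.0 - (3.0 * t**2 - 2.0 * t**3)


def _bump(p: TorsoParams, x, y, cx):
    """One breast mound as a height offset over the sheet."""
    dx = x - cx
    dy = y - p.breast_center_y
    r = np.hypot(dx, dy)
    rho = r / p.breast_radius
    # polar angle from straight down; even in dx so both sides share it
    with np.errstate(invalid="ignore"):
        phi = np.degrees(np.arctan2(np.abs(dx), -dy))
    phi = np.where(r == 0, 0.0, phi)
    e = _envelope(phi)
    prof = (1.0 - e) * _profile_smooth(rho) + e * _profile_fold(rho)
    # the upper pole projects little: fade the outer-annulus amplitude with
    # angle (ramping in with radius so the apex is untouched) to keep the
    # smooth blend's residual concavity below the flat-region variability
    a = _upper_amplitude(phi)
    ramp = np.clip(rho, 0.0, 1.0) ** 2 * (3.0 - 2.0 * np.clip(rho, 0.0, 1.0))
    groove = p.groove_depth * e * np.exp(
        -0.5 * ((r - p.breast_radius) / p.groove_sigma) ** 2
    )
    return p.protrusion * prof * (1.0 - (1.0 - a) * ramp) - groove


def _surface_z(p: TorsoParams, x, y):
    return (
        _base_z(p, x, y)
        + _bump(p, x, y, p.breast_offset_x)
        + _bump(p, x, y, -p.breast_offset_x)
    )


def _warp_w(p: TorsoParams, z):
    """Saturating C2 shear profile: 0 below z0, 1 above z0 + ramp.

    A quintic smootherstep, so the most protruding part of the mound
    translates down rigidly (no added curvature on the plateau) while the
    transition band is gentle enough that the shear onset stays much weaker
    than the fold.
    """
    t = np.clip((np.asarray(z, dtype=float) - p.warp_z0) / p.warp_ramp, 0.0, 1.0)
    return t**3 * (t * (6.0 * t - 15.0) + 10.0)


def _warp_y(p: TorsoParams, y, z):
    return y - p.sag * _warp_w(p, z)


# ---------------------------------------------------------------------------
# analytic ground truth


def _crease_annotation(p: TorsoParams, side: str) -> ContourAnnotation:
    cx = p.breast_offset_x if side == "right" else -p.breast_offset_x
    phi = np.radians(np.arange(-CREASE_GT_DEG, CREASE_GT_DEG + 0.5, 1.0))
    sgn = 1.0 if side == "right" else -1.0
    x = cx + sgn * p.breast_radius * np.sin(phi)
    y = p.breast_center_y - p.breast_radius * np.cos(phi)
    phi_deg = np.degrees(np.abs(phi))
    z = _base_z(p, x, y) - p.groove_depth * _envelope(phi_deg)
    yw = _warp_y(p, y, z)  # the fold rides the ptosis shear; still closed form
    return ContourAnnotation(points=np.column_stack([x, yw, z]), label=f"crease_{side}")


def _overhang_min(p: TorsoParams, side: str):
    """Lowest point of the warped overhang surface (the analytic LVP).

    Minimises the closed-form warped height Y(x, y) = y - sag * w(z(x, y))
    over the mound's support disk.  The minimiser is slightly medial of the
    mound meridian because the chest-wall sheet (and hence the shear) is
    higher toward the sternum.  At the minimum the surface normal points
    straight down, so the point always lies inside the detection cone.
    """
    cx = p.breast_offset_x if side == "right" else -p.breast_offset_x
    cy, rb = p.breast_center_y, p.breast_radius

    def warped_y_vec(x, y):
        return _warp_y(p, y, _surface_z(p, x, y))

    # coarse grid over the lower half of the support disk, then refinement
    gx = np.linspace(cx - 0.8 * rb, cx + 0.8 * rb, 161)
    gy = np.linspace(cy - rb, cy, 201)
    X, Yp = np.meshgrid(gx, gy, indexing="ij")
    vals = warped_y_vec(X, Yp)
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    from scipy.optimize import minimize

    res = minimize(
        lambda v: float(warped_y_vec(v[0], v[1])),
        x0=[X[i, j], Yp[i, j]],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12},
    )
    x_star, y_star = float(res.x[0]), float(res.x[1])
    z_star = float(_surface_z(p, x_star, y_star))
    return np.array([x_star, float(warped_y_vec(x_star, y_star)), z_star])


# ---------------------------------------------------------------------------
# meshing


def _grid_mesh(p: TorsoParams):
    """Regular triangulated grid, exactly symmetric about x = 0.

    The number of vertex columns is even (no vertex on the midline except the
    fan centres of the central quad column); quads are split along alternating
    diagonals whose direction flips with the sign of x, and the central column
    is split into 4-triangle fans, so the face set is exactly x-mirror
    symmetric.
    """
    h = p.edge_length
    nx = 2 * int(round(p.half_width / h))
    ny = int(round(p.height / h)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * h
    ys = np.arange(ny) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts_xy = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):
        return i * ny + j

    ic = nx // 2 - 1  # central quad column (spans x in [-h/2, h/2])
    faces = []
    I, J = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    I, J = I.ravel(), J.ravel()
    centers = []
    center_ids = []
    next_vid = nx * ny
    v00, v10, v01, v11 = vid(I, J), vid(I + 1, J), vid(I, J + 1), vid(I + 1, J + 1)
    xc = (xs[I] + xs[I + 1]) / 2.0
    parity = (I + J) % 2
    split = np.where(xc > 0, parity, 1 - parity)
    for k in range(len(I)):
        if I[k] == ic:
            centers.append([0.0, ys[J[k]] + h / 2.0])
            c = next_vid
            next_vid += 1
            center_ids.append(c)
            faces += [
                [v00[k], v10[k], c],
                [v10[k], v11[k], c],
                [v11[k], v01[k], c],
                [v01[k], v00[k], c],
            ]
        elif split[k] == 0:
            faces += [[v00[k], v10[k], v11[k]], [v00[k], v11[k], v01[k]]]
        else:
            faces += [[v00[k], v10[k], v01[k]], [v10[k], v11[k], v01[k]]]
    if centers:
        verts_xy = np.vstack([verts_xy, np.asarray(centers)])
    return verts_xy, np.asarray(faces, dtype=np.int64)


def _noise_field(p: TorsoParams, xy: np.ndarray, rng: np.random.Generator):
    """Band-limited random field, even in x, scaled to RMS = noise_mm."""
    if p.noise_mm == 0:
        return np.zeros(len(xy))
    K = 40
    kmag = (2 * np.pi / p.noise_wavelength) * rng.uniform(0.75, 1.3, size=K)
    psi = rng.uniform(0.0, np.pi / 2.0, size=K)
    phase = rng.uniform(0.0, 2 * np.pi, size=K)
    amp = rng.normal(size=K)
    kx = kmag * np.cos(psi)
    ky = kmag * np.sin(psi)
    f = np.zeros(len(xy))
    for k in range(K):
        f += amp[k] * np.cos(kx[k] * xy[:, 0]) * np.cos(ky[k] * xy[:, 1] + phase[k])
    rms = np.sqrt(np.mean(f**2))
    if rms == 0:
        return np.zeros(len(xy))
    return f * (p.noise_mm / rms)


def generate_torso(params: TorsoParams) -> SyntheticCase:
    """Generate a torso mesh plus analytic crease and LVP ground truth.

    Identical parameters (including the seed) give a bit-identical mesh.
    """
    params.validate()
    p = params
    xy, faces = _grid_mesh(p)
    x, y = xy[:, 0], xy[:, 1]
    z = _surface_z(p, x, y)
    yw = _warp_y(p, y, z)
    vertices = np.column_stack([x, yw, z])

    mesh = TriangleMesh(vertices=vertices, faces=faces, provenance="synthetic")
    if p.noise_mm > 0:
        from .curvature import vertex_normals  # local import: avoid cycle

        rng = np.random.default_rng(p.seed)
        disp = _noise_field(p, xy, rng)
        normals = vertex_normals(mesh)
        vertices = vertices + disp[:, None] * normals
        mesh = TriangleMesh(vertices=vertices, faces=faces, provenance="synthetic")

    if p.hole is not None:
        hx, hy, hr = p.hole
        inside = (xy[:, 0] - hx) ** 2 + (xy[:, 1] - hy) ** 2 < hr**2
        keep = ~inside[faces].all(axis=1)
        faces = faces[keep]
        used = np.unique(faces)
        remap = np.full(len(vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        mesh = TriangleMesh(
            vertices=mesh.vertices[used], faces=remap[faces], provenance="synthetic"
        )

    crease = {side: _crease_annotation(p, side) for side in ("left", "right")}
    lvp = {
        side: (_overhang_min(p, side) if p.grade >= 1 else None)
        for side in ("left", "right")
    }
    return SyntheticCase(mesh=mesh, crease=crease, lvp=lvp, params=p)


# ---------------------------------------------------------------------------
# analytic curvature fixtures


def _offset_grid_faces(nu: int, nv: int, wrap_u: bool = False):
    """Faces for rows of ``nu`` points where odd rows are offset by +1/2.

    With row spacing ``edge * sqrt(3)/2`` this yields a near-equilateral
    triangulation, which keeps the one-ring curvature estimate isotropic
    (right-angle grids make it strongly direction-dependent per vertex).
    Vertex id = j * nu + i (row-major by row j).
    """
    faces = []
    nu_eff = nu if wrap_u else nu - 1
    for j in range(nv - 1):
        for i in range(nu_eff):
            i1 = (i + 1) % nu
            v00 = j * nu + i
            v10 = j * nu + i1
            v01 = (j + 1) * nu + i
            v11 = (j + 1) * nu + i1
            if j % 2 == 0:  # upper row shifted right by half a step
                faces += [[v00, v10, v01], [v10, v11, v01]]
            else:  # upper row shifted left
                faces += [[v00, v10, v11], [v00, v11, v01]]
    return np.asarray(faces, dtype=np.int64)


def generate_analytic_surface(kind: str, size: float, edge: float) -> TriangleMesh:
    """Triangulated surfaces with analytically known principal curvatures.

    kind="sphere": a spherical cap of radius ``size`` (aperture 0.75 * size),
    curvatures (1/size, 1/size).  A cap with regular connectivity is used
    rather than a full icosphere: an icosphere necessarily contains 12
    irregular (valence-5) vertices at which any one-ring estimator is locally
    biased, which would test the mesh singularity rather than the surface.
    kind="cylinder": radius ``size``, axis y, curvatures (1/size, 0).
    kind="plane": square of half-extent ``size``, curvatures (0, 0).
    kind="saddle": z = (x^2 - y^2) / (2 size); at the centre (1/size, -1/size).
    """
    if size <= 0 or edge <= 0:
        raise ValidationError("size and edge must be positive")
    if kind == "sphere":
        a = 0.75 * size
        nu = max(4, int(round(2 * a / edge)) + 1)
        dy = edge * np.sqrt(3) / 2.0
        nv = max(4, int(round(2 * a / dy)) + 1)
        rows = []
        for j in range(nv):
            off = 0.5 * edge if j % 2 else 0.0
            xr = -a + np.arange(nu) * edge + off
            yr = np.full(nu, -a + j * dy)
            rows.append(np.column_stack([xr, yr]))
        xy = np.vstack(rows)
        rho2 = (xy**2).sum(axis=1)
        keep = rho2 < a * a
        verts = np.column_stack(
            [xy[:, 0], xy[:, 1], np.sqrt(np.clip(size**2 - rho2, 0.0, None))]
        )
        faces = _offset_grid_faces(nu, nv)
        faces = faces[keep[faces].all(axis=1)]
        used = np.unique(faces)
        remap = np.full(len(verts), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(
            vertices=verts[used], faces=remap[faces], provenance="synthetic"
        )
    if kind == "cylinder":
        ntheta = max(8, int(round(2 * np.pi * size / edge)))
        dtheta = 2 * np.pi / ntheta
        length = 3.0 * size
        dy = edge * np.sqrt(3) / 2.0
        nyv = max(4, int(round(length / dy)) + 1)
        rows = []
        for j in range(nyv):
            off = 0.5 * dtheta if j % 2 else 0.0
            theta = np.arange(ntheta) * dtheta + off
            yj = np.full(ntheta, -length / 2 + j * dy)
            rows.append(
                np.column_stack([size * np.sin(theta), yj, size * np.cos(theta)])
            )
        verts = np.vstack(rows)
        faces = _offset_grid_faces(ntheta, nyv, wrap_u=True)
        mesh = TriangleMesh(vertices=verts, faces=faces, provenance="synthetic")
        # orient outward (radial)
        fn = mesh.face_normals()
        centroids = verts[faces].mean(axis=1)
        radial = centroids.copy()
        radial[:, 1] = 0
        if np.einsum("ij,ij->i", fn, radial).mean() < 0:
            mesh.faces = mesh.faces[:, ::-1]
        return mesh
    if kind in ("plane", "saddle"):
        nu = max(4, int(round(2 * size / edge)) + 1)
        dy = edge * np.sqrt(3) / 2.0
        nv = max(4, int(round(2 * size / dy)) + 1)
        rows = []
        for j in range(nv):
            off = 0.5 * edge if j % 2 else 0.0
            xr = -size + np.arange(nu) * edge + off
            yr = np.full(nu, -size + j * dy)
            rows.append(np.column_stack([xr, yr]))
        xy = np.vstack(rows)
        if kind == "plane":
            zc = np.zeros(len(xy))
        else:
            zc = (xy[:, 0] ** 2 - xy[:, 1] ** 2) / (2.0 * size)
        verts = np.column_stack([xy[:, 0], xy[:, 1], zc])
        faces = _offset_grid_faces(nu, nv)
        return TriangleMesh(vertices=verts, faces=faces, provenance="synthetic")
    raise ValidationError(f"unknown analytic surface kind: {kind!r}")


# ---------------------------------------------------------------------------
# case export


def write_case(case: SyntheticCase, out_dir, mesh_format: str = "ply") -> dict:
    """Write mesh + ground-truth files; return the manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mesh_path = out_dir / f"torso.{mesh_format}"
    save_mesh(case.mesh, mesh_path)
    entry = {
        "mesh": mesh_path.name,
        "params": asdict(case.params),
        "crease": {},
        "lvp": {},
    }
    for side, ann in case.crease.items():
        fname = f"crease_{side}.txt"
        write_annotation(ann, out_dir / fname)
        entry["crease"][side] = fname
    for side, point in case.lvp.items():
        entry["lvp"][side] = None if point is None else [float(v) for v in point]
    (out_dir / "case.json").write_text(json.dumps(entry, indent=2, sort_keys=True))
    return entry
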