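# Methods

## Problem and coordinate conventions

Given a triangle-mesh surface scan of a female torso, cropped to a region of
interest from below the neck to just above the umbilicus, the package detects
per breast (a) the inferior breast-chest contour — the concave crease along
which the lower breast meets or hangs against the chest wall — and (b) the
lowest visible point of the breast overhang. All coordinates are millimetres.
The frame is **+y superior, +z anterior, +x anatomical left**; "down",
"lowest" and "above" are defined against this frame, and the gravity axis is
−y. Meshes whose bounding-box diagonal is below 10 are assumed to be in
metres and are rescaled with a warning. Face winding is validated and
reoriented so normals point outward (positive enclosed volume for closed
meshes; positive mean anterior z-component for open patches).

## Detection pipeline

### Principal curvatures and shape index

Curvatures are estimated with the normal-cycle tensor estimator: at each
vertex v,

    T(v) = (1 / A_v) Σ_{e ∋ v} β(e) · (|e|/2) · ê êᵀ,

summing over the edges incident to v, with β(e) the signed dihedral angle at
edge e (positive at convex edges under the outward-normal convention), ê the
unit edge direction, |e|/2 the edge length inside v's barycentric cell and
A_v the barycentric cell area. The eigenvector of T closest to the vertex
normal is discarded; the remaining two eigenvalues estimate {k_max, k_min}
(the tensor pairs each eigenvalue with the orthogonal principal direction,
which permutes directions but not the value set). Convex regions have
positive curvatures. Vertex normals are the renormalised sum of one-ring
unit face normals, with an area-weighted fallback where the plain sum
cancels.

The estimator is validated per vertex against analytic surfaces (sphere,
cylinder, plane, saddle) to within 10% at 1.5 mm resolution. Two estimator
facts shaped the fixtures: on right-angle structured grids the one-ring
estimate is strongly direction-dependent per vertex, so the fixtures use
offset (near-equilateral) triangulations; and at irregular-valence vertices
(the 12 valence-5 vertices of any icosphere) a one-ring estimate carries an
inherent ~15% bias, so the sphere fixture is a spherical cap with regular
interior connectivity.

The shape index is S = (2/π)·atan((k_max + k_min) / (k_max − k_min)). If
|k_max − k_min| < 1e−9 /mm the continuous limit is used: S = sign(k_max +
k_min), and S = 0 if the sum is also below 1e−9 (a flat vertex). S is
scale-free: convex mounds approach +1, concave creases are negative.

### Candidate points

sPP = { p : S(p) < 0 and k_min(p) < k_mean }, with k_mean the mean of k_min
over all non-rim ROI vertices. The second condition removes nearly flat
vertices whose S is negative only through mild undulation. Rim (open
boundary) vertices are excluded both from k_mean and from candidacy: the ROI
crop leaves an artificial border whose truncated one-rings produce spurious
strong concavity that the tracer would otherwise follow as a fake crease.
Scattered candidates elsewhere on the torso are expected and left alone; the
tracing stage is responsible for ignoring them.

### Reference point

Each half of the torso (split at the midline x, ties to the right) is tiled
into 5 mm × 5 mm blocks in the x-y plane. Block x-edges are anchored at the
ROI midline — for the right half this is its minimal-x corner, and midline
anchoring makes the whole construction exactly equivariant under mirroring —
and y-edges at the side's minimum y. Each block i scores

    ave_S_i = Σ_j S_ij · z_ij / n_i,     z_ij = z_orig,ij − z_min(side) ≥ 0.

The depth weighting favours convex regions that project forward: block A
(largest ave_S) sits on the breast mound. A window of A's column ± 3 columns
(± 15 mm) by 10 rows (50 mm) *above* A is scanned; the highest block with
ave_S > 0 is block B, and RP = (x of A's centre, y of B's centre). The
window keeps RP laterally near the mound while lifting it above the contour
even for ptotic breasts. If no window block is positive, B falls back to A
with a warning (flat or absent mounds). Ties for A and for equal-height B
candidates resolve bottom row first, then the column nearest the midline.
No nipple is involved anywhere.

At 5 mm blocks and the intended point spacing (≤ 2 mm) a block holds ~9+
vertices; the block statistics degrade below that density.

### Contour tracing

Candidate angles about RP use v1 = (0, −1) and v2 = (x_p − x_RP, y_p −
y_RP):

    θ = sign(x_p − x_RP) · acos(v1·v2 / |v1||v2|)   (sign(0) := +1),

so θ = 0 points straight down; candidates sort by θ and partition into 5°
sectors (sector k covers [5k − 2.5°, 5k + 2.5°)). A candidate coinciding
with RP in (x, y) gets θ = 0 with a warning.

In sector 0, each candidate's NOA is the largest angle between its one-ring
vertex normal and that of any other candidate within 10 mm (Euclidean, 3D);
candidates with no neighbour in range have undefined NOA. The candidate M
with maximal NOA marks the sharpest shape change below RP; the candidate
within 10 mm of M with minimal k_min (possibly M itself) becomes the
intermediate point — the first accepted contour point. An empty or singleton
sector 0, or one with no 10 mm pair, aborts detection for that breast.

Extension proceeds from the intermediate point's sector outward in both
angular directions independently. In each next sector the accepted point is
the candidate with minimal k_min among those whose 3D distance to the
previously accepted point is strictly below 2L, where L = (5°·π/180°)·R and
R is the planar (x, y) distance from RP to the previous point (R ≈ radius of
the contour arc in that sector; e.g. R = 114.59 mm gives L = 10.0 mm). An
empty sector, or no candidate within 2L, terminates that direction; the
reason is recorded. A hard stop at ±120° guards against wrap-around —
anthropometrically the breast base never subtends more than that about RP.
Equal k_min ties resolve to the smaller vertex index (determinism).

The detected points, ordered by θ, are interpolated by a natural cubic
spline per coordinate over the cumulative chord-length parameter and sampled
at 200 evenly spaced parameter values. At least 4 detected points are
required. An independent `verify_chain` walk re-checks the 2L constraint on
every result.

### Lowest visible point

Faces whose unit normal lies within a 10° cone of −y are collected; their
vertices are filtered to x strictly between the contour's two endpoint
knots, and the minimum-y survivor is the LVP (ties to the smaller vertex
index). If no face points downward the breast has no overhang — ptosis
grade 0 — and the LVP is reported absent: the fold itself is then the lowest
visible contour. The cone axis is configurable (+z available) because the
published description names the z-axis while using "lowest y-value"; the
gravity axis −y is the default and the consistent reading.

### Agreement metrics

Both contours are spline-resampled to 200 points (length normalisation).
`ave_d` = (Σ_i d(A_i) + Σ_j d(B_j)) / (|A| + |B|), with d(·) the nearest
point distance to the other set — symmetric by construction. `Dc(t)` is the
fraction of points of both sets with d < t (strict), reported at t = 0.5, 1,
2, 3, 4, 5 mm by default; it is non-decreasing in t.

## Synthetic test bed

The clinical scans this class of method is built for are not publicly
available, so validation uses a parametric torso generator whose ground
truth is *analytic* — extracted from the closed-form surface, never from the
mesh.

Geometry: a gently convex chest-wall sheet z = base(x, y) carries one
compact-support mound per side (default support radius 60 mm, protrusion
45 mm, centres at x = ±72, y = 165 on a 320 × 300 mm sheet). The radial
profile morphs with the polar angle φ from straight down:

* |φ| ≤ 95°: profile (1 − ρ²)^{3/2}, monotone from a convex apex to a
  tangential rim contact whose bending concentrates at the support circle,
  plus a narrow groove (depth 1.5 mm, σ = 2 mm) centred exactly on the
  circle — the sharp skin fold of an inframammary crease. At 1.5 mm edges
  the resolved fold curvature is ≈ −0.5 /mm, several times any other
  concavity on the surface.
* Above 95° the profile blends into (1 − ρ²)³ (curvature-free rim) and the
  outer-annulus amplitude fades to 0.10 by 125°: the upper pole projects
  little and shows no visible boundary, and — materially for testing — any
  compact C² blend of full amplitude would leave a concave annulus strong
  enough to qualify as candidate points.

Ptosis is a shear of ambient space, y → y − sag·w(z), with w a quintic
smootherstep ramping from 0 at z₀ = 40 mm (just below the fold level) to 1
over 48 mm: the protruding mound drops quasi-rigidly by `sag` (0 / 39.5 /
47.5 / 58.6 mm for grades 0-3) while the chest wall stays put. A shear of
space is a bijection, so the mesh cannot self-intersect; the fold circle
rides the shear, so the ground-truth crease is the closed-form warped
circle; and the saturating profile keeps the shear-onset "tuck" much weaker
than the fold. The grade coefficients were fixed from the analytic
mid-sagittal profile so the overhang bottom sits ~3 / 10 / 20 mm below the
fold for grades 1 / 2 / 3; grade 0 has a maximum slope of ~49°, leaving no
face within the 10° downward cone.

Ground truth: the crease annotation samples the warped support circle over
±120° from the lowest fold point (the fold stays curvature-dominant over
that arc; beyond ~125° it fades out by construction). The LVP is the
minimiser of the closed-form warped height Y(x, y) over the mound's support
disk, located by a dense grid scan plus Nelder-Mead refinement of the
analytic function — mesh-independent to solver tolerance. The minimiser
sits slightly medial of the mound meridian because the chest wall (and
hence the shear) is higher toward the sternum.

Meshing: a regular grid at 1.5 mm default edge length (point spacing well
inside the ≤ 2 mm the block statistics assume), triangulated with
alternating diagonals whose direction flips with the sign of x and a
4-triangle fan in the central column, so symmetric parameter sets produce
exactly mirror-symmetric meshes (bitwise for noiseless surfaces, to ~1e−9
once noise rides on accumulated vertex normals). Optional circular holes
emulate scan dropouts; the pipeline refuses to run a breast whose lower
half contains an interior boundary loop.

Noise: scanner residual error is modelled as a band-limited random field
(default wavelength 25 mm — the scale of multi-camera merge artifacts —
RMS equal to the requested amplitude, default 0.3 mm) applied along vertex
normals, with a cosine basis that is even in x so symmetric cases stay
symmetric. Surface reconstruction smooths raw sensor noise below the patch
scale, so the residual error of a real scan mesh is spatially correlated;
white noise of the same amplitude would have second differences above
0.5 /mm at 1.5 mm spacing — it would bury every anatomical curvature and
describes no real scanner.

What the generator does **not** emulate: camera occlusion (the deep crevice
under a severely ptotic breast is fully meshed here, while a real scan
leaves holes or bridges), pose and body-shape variation, asymmetric
breasts, skin texture, and nipples (the method never uses them). Passing
the synthetic panel therefore demonstrates the pipeline's correctness and
its noise robustness on idealised anatomy, not clinical-grade accuracy.

## Validation conditions and results of record

The test suite validates on a panel of 20 cases — ptosis grades 0-3 × five
seeds — at 1.5 mm edges and 0.3 mm noise, requiring ave_d ≤ 2.5 mm and
Dc(3 mm) ≥ 0.7 in at least 18/20 cases (both breasts must pass for a case
to count), LVP within 5 mm on every ptotic breast and no spurious LVP on
grade 0. `scripts/acceptance.py` recomputes the same quantities from
scratch for any seed. Typical numbers: mean ave_d ≈ 1.0-1.3 mm, mean
Dc(3 mm) ≈ 0.95, LVP error ≈ 1.3 mm mean.

## Known limitations

* **Grade 0 is the hardest case.** Flat chest regions have near-zero
  minimum curvature, so under 0.3 mm noise a quarter of their vertices fall
  below k_mean and the tracer can extend past the crease ends, walking
  noise candidates in ≤ 2L steps until the ±120° stop. Grade-0 recovery is
  therefore the most variable (occasionally ave_d ≈ 3-6 mm on a seed); for
  ptotic grades the crease spans the whole traced range and absorbs the
  chain. The ordering — worst on grade 0, best on grade 3 — is inherent to
  a curvature-based detector, which feeds on the sagging crease.
* The depth-weighted block score tilts a little toward the sternum (the
  chest wall rises medially), so RP can sit up to ~3 blocks medial of the
  mound apex; detection is insensitive to this, but the RP position itself
  should not be read as an apex estimate.
* At point spacings beyond ~2 mm the 5 mm block statistics (few vertices
  per block) and the fold resolution both degrade; inputs that sparse are
  outside the method's design envelope.
* Curvature is single-scale (one-ring); no smoothing or multi-scale
  analysis is attempted.
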