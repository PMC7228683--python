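# ibccontour

Automatic detection of the **inferior breast-chest (IBC) contour** — the
visible crease along which the lower breast meets the chest wall — and of the
**lowest visible point (LVP)** of the breast on 3D triangle-mesh surface scans
of the female torso.

Both landmarks anchor quantitative breast morphometry (symmetry, volume,
ptosis grading) in reconstructive and cosmetic surgery, but tracing them by
hand on 3D scans is slow and operator-dependent. This package implements a
fully automatic, curvature-based detector plus the two agreement metrics used
to score a detected contour against a reference annotation, and a synthetic
torso generator with analytic ground truth for validation.

## Method

Meshes are in millimetres with +y superior, +z anterior, +x the subject's
anatomical left. For a cropped torso region of interest:

1. **Curvature.** Per-vertex principal curvatures (k_max, k_min) via the
   normal-cycle tensor integrated over one-ring neighbourhoods, and the shape
   index S = (2/π)·atan((k_max + k_min)/(k_max − k_min)) ∈ [−1, 1] —
   positive on convex mounds, negative in concave creases.
2. **Candidates.** sPP = { p : S(p) < 0 and k_min(p) < k_mean }, where k_mean
   is the ROI-wide mean of k_min; the second condition removes near-flat
   undulation.
3. **Reference point (RP).** Each torso half is tiled into 5 mm × 5 mm
   blocks scored by the depth-weighted shape index
   ave_S = Σ S·(z − z_min)/n. Block A maximises ave_S (the forward-projecting
   convex mound); the highest positive block in a 7 × 10-block window above A
   gives the RP height: RP = (x_A, y_B).
4. **Contour tracing.** Candidates get angles θ about RP (θ = 0 straight
   down) and are split into 5° sectors. In the sector below RP the point with
   the maximal normal-angle (NOA, sharpest shape change within a 10 mm
   neighbourhood) seeds the search; the candidate with minimum k_min within
   10 mm of it is the first contour point. The contour is then extended
   sector by sector in both directions: each sector contributes its
   minimum-k_min candidate closer than 2L to the previous point, with
   L = (5°·π/180°)·R the sector arc length at the RP distance R. A natural
   cubic spline through the detected points is the IBC contour.
5. **LVP.** Vertices of faces whose normal lies within 10° of straight down,
   filtered laterally between the contour endpoints; the lowest-y survivor is
   the LVP. No downward face means no overhang (ptosis grade 0): the LVP is
   reported absent and the fold itself is the lowest visible contour.

**Metrics.** Contours are spline-resampled to 200 points each; `ave_d` is the
symmetric mean nearest-point distance, and the dice coefficient `Dc(t)` is
the fraction of points of both contours whose nearest-other-contour distance
is strictly below the threshold t.

See `docs/methods.md` for the model details, the synthetic test bed, and the
design decisions.

## Worked example

Generate a grade-2 ptosis torso (known ground truth), detect, and evaluate:

```bash
$ ibc simulate --grades 2 --n 1 --seed 7 --out cases
wrote 1 case(s) to cases (manifest.json)

$ ibc detect cases/grade2_seed7/torso.ply --out detected
detected 2 side(s); results in detected

$ ibc evaluate detected/torso_right_contour_spline.txt \
               cases/grade2_seed7/crease_right.txt
ave_d = 0.9254 mm
Dc(<0.5 mm) = 0.3700
Dc(<1 mm) = 0.8575
Dc(<2 mm) = 0.9550
Dc(<3 mm) = 0.9600
Dc(<4 mm) = 0.9675
Dc(<5 mm) = 0.9725
```

The detected right contour lies on average 0.93 mm from the analytic crease
and 96% of resampled points agree within 3 mm. `detected/report.json`
records the run: the reference point at (62.5, 165.6) mm, 49 detected
contour points, and the LVP at (68.3, 94.7, 76.4) mm — about 10 mm below the
lowest crease point, as expected for a grade-2 overhang. For a grade-0 case
(`--grades 0`) the LVP files report `absent` instead.

`ibc detect` accepts PLY and OBJ meshes; reference contours are plain-text
`x y z` lines (mm), so manual annotations from any tool can be evaluated the
same way.

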