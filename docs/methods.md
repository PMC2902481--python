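# Methods

`lymphatlas` implements a reference-based (single-atlas-per-target)
delineation pipeline for cervical lymph node regions: segment landmark
structures in 3D volumes, retrieve the geometrically most similar
reference subject from a database, register reference to target with a
landmark-initialized B-spline / mutual-information method, project the
reference's expert-drawn regions onto the target, and evaluate the
projections with Dice overlap and surface distances.  This note records
the models, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## Transform model

The registration transform is a rigid motion plus a cubic B-spline
free-form deformation (FFD):

    g(x | mu) = R (x - x_C) + x_C + T + D(x | delta)

* `R` — rotation from roll-pitch-yaw Euler angles `(gamma, theta, phi)`
  composed `R = Rz(gamma) Ry(theta) Rx(phi)`, about the volume center
  `x_C`; `T` — translation (mm).
* `D` — tensor-product cubic B-spline interpolation of per-control-point
  3-vector coefficients `delta_j` on a uniform grid.  A resolution
  `rho = (rho_x, rho_y, rho_z)` places `rho_d` interior control points
  per axis at spacing `q_d * s_d / rho_d` (`q` image dims, `s` voxel
  spacing), so `[15, 15, 11]` means 2475 interior control points; the
  stored lattice carries one ghost ring before and two after so the
  cubic support covers the whole extent.  The full parameter vector
  `mu` has `6 + 3 * rho_x * rho_y * rho_z` entries.

**Direction.** `g` maps a point of the *target* subject's frame to the
matching location in the *reference* subject's frame
(`reference(g(x)) ≈ target(x)`).  This is the composition region
projection needs — each target voxel center is pushed through `g` and
the label looked up in the reference mask with nearest-neighbor
sampling — and is stated explicitly because forward/inverse conventions
are the classic registration bug.

**Spline numerics.**  Coefficient storage matches ITK's
`BSplineTransform` lattice exactly (verified to 1e-15 against
`SimpleITK`), which lets the optimizer work on the same parameters this
package defines.  Evaluation uses `scipy.ndimage.map_coordinates`
(order 3, `prefilter=False`) on the coefficient lattice; interpolating
coefficients for prescribed lattice values come from
`scipy.ndimage.spline_filter1d` with the mirror boundary rule.  Grid
refinement samples the coarse field at the fine lattice and re-fits
interpolating coefficients; because a cubic spline is not exactly
representable on a non-nested finer knot grid, refinement carries a
2–4 % (of coefficient RMS) residual, largest near the extent's edges.
This residual is irrelevant in practice: refinement only seeds the next
optimization level.

## Registration

1. **Rigid stage.**  Mattes mutual information (50 histogram bins, 5 %
   random voxel sampling with a fixed seed) over the six rigid
   parameters, optimized by regular-step gradient descent with physical
   shift scaling on a 3-level image pyramid (shrink 4/2/1).
2. **Deformable stage.**  The reference is resampled once through the
   rigid map; a B-spline grid over the target geometry is then refined
   through a coarse-to-fine schedule (default [6,6,5] → [10,10,8] →
   [15,15,11]) with Mattes MI and L-BFGS-B at each level, on an image
   pyramid (shrink 4/2/1, smoothing 2/1/0 voxels).  The final level runs
   at full image resolution: empirically the optimizer's accuracy floor
   scales with the sampled voxel size, and a shrink-2 final level
   plateaus near 1.5 mm regardless of initialization.  Because the
   B-spline field is learned in the rigidly-resampled frame, its
   coefficient vectors are rotated by `R` when folded back into the
   additive model above (the two parameterizations are exactly
   equivalent; the rotation is linear in the coefficients).
3. **Landmark initialization.**  Given correspondence pairs (reference
   surface point, matched target location), at the start of every level
   each control point with a landmark within the proximity radius takes
   the deformation vector of its nearest landmark; all other lattice
   values are kept, and interpolating coefficients are re-fit.  The
   assignment is deliberately piecewise-constant and may be rough; the
   subsequent MI optimization smooths it.  The proximity radius default
   is 25 mm — "close" relative to the coarsest control spacing (~32 mm)
   so that a surface deformation is never smeared onto control points
   more than one cell away.

Failure is flagged (not silently accepted) on a non-finite metric; the
per-level metric trace of accepted optimizer steps is returned for
inspection.

## Structure segmentation

Landmark structures are found progressively, in descending order of
detection reliability.  Per structure, a rule holds an intensity
window, a 2D size window, negative shape constraints (max second-moment
elongation, min solidity), and an optional location prior relative to
an earlier structure.  Each axial slice is swept with 8 evenly spaced
thresholds (high to low); the first threshold producing a
constraint-satisfying connected component contributes that component as
a seed.  Seeds grow with a morphological geodesic active contour
(inverse-gradient speed, positive balloon), unioned with the seed so
growth is monotone; the largest connected component is kept because
same-intensity structures (all bone) can contribute fringe seeds.
Sub-optimal thresholds and partial growth are acceptable by design —
the output is landmark geometry, not clinical segmentation.  The
default rules' numeric windows are configuration for the synthetic
phantom's CT-like intensities; real-CT rule sets would tune them per
scanner protocol.

## Surface correspondence

For homologous structure surfaces A (reference) and B (target) the
per-vertex displacement field f minimizes

    E = E_sim + alpha * E_str + beta * E_pri,
    alpha = 0.001, beta = 0.0001,

with `E_sim` the mean squared distance of mapped points to B, `E_str`
the mean squared graph-Laplacian of f over A's mesh graph (distortion),
and `E_pri` the mean squared displacement (plausibility prior).  The
three roles (similarity, structural distortion, deformation
plausibility) are conventional in surface-correspondence methods; the
quadratic forms above are this package's concrete choice — the part of
the pipeline with the most design freedom — made so each descent step
is one sparse linear solve.  Optimization is
majorize-minimize block coordinate descent: exact closest-point
assignment, then a Laplacian-regularized solve, which makes the total
energy non-increasing.  The field is initialized with an ICP rigid
alignment of A onto B: closest-point assignment alone cannot observe
tangential motion (points slide to the nearest patch, tying `E_sim`
without fixing the correspondence), while the rigid bulk is exactly
what ICP recovers; the descent then refines the non-rigid residual.
Landmark pairs for registration are area-weighted vertex samples with
their displacement vectors; multiple structures are corresponded
independently and concatenated.

## Similarity retrieval

Per subject, the feature vector holds: body volume (cm³) and
bounding-box extents (mm); mandible and outer-body surface meshes; the
3D mandible→hyoid centroid offset; 2D hyoid→jugular and hyoid→spine
offsets on the axial slice at the hyoid centroid; normalized hyoid and
mandible centroid locations in the body box; and two vertical distances
(superior body plane→mandible, mandible→hyoid).  The superior
body-extent plane stands in for the skull base, which a neck-limited
field of view cannot image.  The distance is

    D_F = sqrt( sum_i w_i d_i^2 )

with absolute differences for scalars, Euclidean norms for vectors,
and for the two mesh features the directional Hausdorff distance after
ICP pre-alignment (sampled area-uniformly, 5000 points by default;
directional reference→target, making those two terms asymmetric — the
rest of `D_F` is symmetric).  Default weights grade a heavy-to-light
priority on a 10…0.1 scale: hyoid-location features 10, mandible mesh
5, vertical distances 2, body contour/volume 0.5, remainder 0.1 —
hyoid position is the strongest single predictor of nodal-level
geometry, the mandible mesh the strongest shape cue; they are
configuration, not fitted values.  References sorted by ascending `D_F` give the feature ranking
`R_F`; sorting by the post-registration Hausdorff outcome gives `R_I`,
and the agreement statistic is the distribution of `R_F`'s top-1
position within `R_I` (bins 1 / 2 / 3 / >3).

ICP subsamples source sets above 2000 points (deterministically): six
rigid parameters do not need tens of thousands of correspondences.
Point-to-mesh distances are exact point-to-triangle minima (plane
projection with edge clamping); meshes above 1500 faces are shortlisted
through a KD-tree over face centroids with a conservative radius bound,
so the shortlist provably never misses the true minimum.

## Evaluation

Dice uses voxel counts; two empty masks score 1.0 (agreement on
absence; the ratio is otherwise 0/0).  Projected-vs-truth surface
distances are directional (projected→truth), reported in cm, and use
*no* ICP pre-alignment — both regions already share the target frame,
and pre-aligning would hide exactly the registration error being
measured.  Correlation between `D_F` and `D_H` is Pearson's r
(Spearman available as an option).

## Synthetic phantom cohort

Clinical CT cohorts with expert contours cannot be shipped, so the
package generates neck-like phantoms: an ellipsoidal soft-tissue body
(~40 intensity units) in air (−1000) containing a posterior bone tube
(spine, 700), a flattened anterior bone ellipsoid (mandible), a small
bone ellipsoid (hyoid), four lateral contrast tubes (jugular/carotid,
200), and four soft nodal-region ellipsoids (levels 1B/2, left/right)
standing in for expert contours.  Primitives are analytic and
rasterized at voxel centers, so expected volumes/centroids are exact
for oracle tests.  The default grid is 96×96×72 voxels at
2×2×2.5 mm (≈19×19×18 cm field of view) — a desk-scale stand-in for
512² clinical CT.

Two realism parameters matter:

* **Gaussian noise** (SD 10) on the intensity volume only.
* **Soft-tissue texture**: a smooth random field (SD 50, 8 mm
  correlation length) added inside the body.  Without it the phantom is
  piecewise constant and interior deformation is *unidentifiable* for
  any intensity-driven metric — every warp that fixes structure
  boundaries leaves the image unchanged up to noise — so interior
  recovery error would measure nothing.  The magnitude matches the
  scale of muscle/fat/gland heterogeneity in real neck CT.  Both are
  zero-able, and the piecewise-constant oracle tests construct their
  specs with texture off.

Inter-subject variation: per-structure pose/scale jitter
(SD 3 mm / 5 %), plus a smooth ground-truth warp that is itself a
cubic B-spline field on a ~40 mm control grid, rescaled so its *peak*
displacement equals the requested amplitude (default 5 mm).  Making
the ground truth representable by the registration model turns
registration tests into parameter-recovery tests with a clean optimum.
Each subject's exact warp is returned (`subject(x) = prewarp(x + D(x))`),
and nodal masks are warped with the same field.  The whole cohort is a
pure function of its spec (one root seed, per-subject derived streams).
A graded-amplitude variant warps one base subject by increasing
amplitudes for retrieval experiments.

**What the phantoms do not emulate:** beam hardening and streak
artifacts, partial-volume mixtures at boundaries, topology differences
between subjects (e.g. surgical resections), intensity
non-correspondence beyond a monotone remap, and anatomically realistic
mandible/vessel shapes.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent under controlled
deformations — not that clinical accuracy figures would be reproduced
on patient data.

## Problem sizes and experiment design choices

The bundled experiments run at desk scale on one CPU: warp-recovery
experiments use the default 96×96×72 phantom with a two-level schedule
([6,6,5] → [10,10,8], 20 L-BFGS-B iterations per level, 5 % sampling)
— the ground-truth warp lives on a ~40 mm grid, which a [10,10,8]
grid (19–23 mm spacing) already over-resolves, so the [15,15,11]
maximum is reserved for the full-size default configuration rather
than the recovery experiments.  Landmark correspondences for the
paired recovery comparison come from the known warp, sampled on all
structure surfaces plus the outer body contour (~2300 points).
Retrieval experiments use a graded cohort (amplitudes 1–8 mm) with
features computed from ground-truth structure masks, isolating the
retrieval question from segmentation quality.  Rank-agreement null
statistics use 10,000 Monte-Carlo permutations.

## Known limitations

* No folding prevention or diffeomorphic guarantee in the FFD; large
  amplitudes can produce locally non-invertible fields (the generator's
  defaults stay in the invertible regime, checked by fixed-point
  inversion residuals < 0.1 voxel).
* Mutual information overfits mildly at fine grid resolutions (it can
  exceed the ground-truth alignment's MI while being farther from the
  truth); no bending-energy regularizer is applied because the
  optimization backend does not expose one.  The multi-level schedule
  and the full-resolution final level keep this in check.
* The correspondence energy's term definitions are inferred (see
  above); with symmetric, feature-poor surfaces (a perfect sphere) the
  tangential component of the correspondence is fundamentally
  unobservable.
* Axis-aligned volumes only (no direction cosines), matching axial CT
  usage; no DICOM/DICOM-RT IO.
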