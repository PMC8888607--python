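# Methods

This note documents the models, numerical choices, and limitations behind
`myoline`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what the
code reproduces.

## Mesh model and measures

Meshes are ordered vertex arrays with ordered polygonal faces
(counter-clockwise from outside) and a length-unit tag (`mm`/`cm`/`m`).
Faces stay polygonal through OBJ and ASCII-PLY I/O — the k-gon structure
of sculpted muscle meshes is meaningful (OBJ `g` groups double as named
attachment selections) — and are triangulated on demand: quads split along
the (v0, v2) diagonal, k-gons fan from v0. This is exact for planar faces;
for non-planar quads the two diagonal splits genuinely differ, and the
(v0, v2) convention is simply fixed. Degenerate (collinear) faces are
excluded with a warning rather than an exception, using a relative area
floor of 1e-12 × the squared bounding-box diagonal. STL import welds
duplicate facet vertices at an absolute tolerance of 1e-9 (configurable).

Closed-mesh volume is the signed sum of origin-tetrahedron volumes over
the triangulated faces, `Σ det(p0, p1, p2)/6`. The sum is
translation/rotation invariant for closed surfaces; a negative total
indicates inward winding and is reported (`MeshReport.negative_volume_flag`)
and corrected by absolute value. Volume and area computations refuse
meshes with boundary edges (edges on exactly one face) or non-manifold
edges (more than two faces), as counted on the polygonal faces.

## Attachment centroids

The attachment centroid is the extrinsic area-weighted mean of triangle
centroids, with triangle areas by Heron's formula from the three side
lengths (the radicand is clamped at zero for near-degenerate triangles,
and triangles below 1e-12 relative area contribute zero weight rather
than noise). Heron areas agree with the cross-product formula to better
than 1e-9 relative on random triangles; the result is invariant to face
order and triangulation choice for planar patches, and equivariant under
rigid motions. For curved patches the centroid can lie off the surface —
deliberately, since it anchors a straight slicing axis rather than
marking a surface point. Fan triangulation assumes each face is
fan-visible from its first vertex (true for convex and mildly non-convex
faces, which is what sculpted muscle meshes contain).

## Line-of-action estimation

Slicing planes are perpendicular to the origin-centroid→insertion-centroid
axis at the interior parameters t_i = i/(n+1), i = 1..n, so no plane
coincides with an attachment cap. Each plane cuts the triangulated mesh in
segments (one per straddling triangle); segment endpoints are merged
within 1e-9 × bounding-box diagonal and chained into closed loops. A plane
passing exactly through vertices is shifted along its normal by the same
1e-9 × diagonal — deterministic, no randomness. Loop area and centroid are
computed from the loop's 2D projection into the plane (valid for
non-convex outlines); multiple disjoint loops combine by area weighting.

Area-weighted combination of disjoint loops reproduces the known artifact
of this slicing approach: near a wide attachment angled to the axis, the
slicing planes cut through the attachment surface and the truncated or
extra loop material drags centroids sideways, producing a kink in the LoA
near that attachment. `estimate_loa(..., nearest_loop=True)` instead keeps
only the loop closest to the axis, as a corrective option that is off by
default. Slices that miss the belly entirely are skipped with a warning;
if more than half are empty the axis is deemed to miss the muscle and the
call errors.

Smoothing fits a cubic least-squares B-spline through the path,
parameterised by cumulative chord length, with very large weights
(1e6 : 1) on the two endpoints and exact endpoint snapping after
evaluation; `smoothing=0` gives the interpolating spline, and paths with
fewer than four points fall back to linear resampling. Arc length is the
polyline length of the raw path or the resampled curve and equals the MTU
length in model units. OpenSim PathPoint export converts model units to
metres.

### Accuracy on known centerlines

On a straight cylinder the slice centroids sit on the axis to machine
precision. On a quarter-circle-arc tube (arc radius 10, tube radius 1,
64 sides, 20 slices) the interior slice centroids track the generating
arc to well under 1% of the tube radius, but the slices nearest the end
caps reach ≈2.3%: the caps of a quarter-arc tube sit at 45° to the
origin–insertion chord, so the near-cap planes clip the attachment caps —
the same oblique-attachment mechanism as the kink artifact, confirmed
against a dense-quadrature oracle on the smooth solid. For the same
reason the *per-slice* worst-case error grows as slices are added (new
planes land ever closer to the oblique caps: 1.1% → 2.0% → 2.3% → 16% of
the tube radius at 5/10/20/40 slices), while the *path-recovery* error —
how closely the threaded polyline tracks the centerline — improves with
slice count as long as the planes stay clear of the cap-clip zone (tested
on a long, gently curved tube whose caps are only 15° off perpendicular).
Practical guidance follows: choose the slice count so the end slices stay
roughly one cap-extent away from oblique attachments, or use
`nearest_loop`/downstream path editing near such attachments.

### The kink fixture

`make_oblique_muscle` builds a prism (length × width × thickness) whose
origin cap tilts by a given angle about the width axis, pivoting on its
own centroid. For this geometry the truncated sections have a closed form
— at axial position x the section is a rectangle spanning z from −t/2 to
min(t/2, x/tan θ) — so the slice-centroid height is the midpoint of that
interval. The implementation matches this oracle to ~1e-9 relative; the
deviation is zero at 0°, signed toward the side the cap leans, and grows
monotonically with cap angle.

## Mass estimation

Mass = volume (converted to m³ via the unit tag) × density. The default
density is 1060 kg/m³, the standard homogeneous fresh-muscle value;
tendon is ~5% denser (1120 kg/m³ default) and enters only through an
explicit muscle/tendon volume partition — partitioning is never inferred
from geometry, and the all-muscle default matches how volumetric models
are usually evaluated. Report tables round mass to 3 decimals (kg).

The bundled gorilla-shoulder table (five muscles: measured dissection
masses and modelled volumes) is the worked evaluation example: modelled
volumes × 1060 kg/m³ reproduce the modelled masses exactly at 3-decimal
rounding, and the summed modelled mass underestimates the summed measured
mass by ≈2.70% when computed from the printed table values (the printed
inputs are themselves rounded, so the recomputed percentage carries that
rounding).

## Agreement statistics

- **Bland–Altman**: differences d = a − b; bias = mean(d); limits of
  agreement = bias ± 1.96·SD(d) (sample SD); the bias CI uses Student's t
  with n−1 df. A reported `bias ± h` is the CI half-width convention, with
  the limits of agreement reported separately.
- **Mann–Whitney U**: W is the U statistic of the first sample (the
  rank-sum convention of standard statistical environments, so printed W
  values are comparable across software). The p-value is exact (full
  enumeration) when both samples have ≤8 observations and no ties —
  verified against an independent brute-force enumeration for every
  sample-size pair up to 7 — otherwise a normal approximation with
  midranks, tie correction, and continuity correction. Two-sided only.
- **Within-range summary**: per muscle, the reference measurements define
  mean±1SD, mean±2SD, [min, max], and [min−20%·|min|, max+20%·|max|]
  intervals (SD intervals centred on the mean — the standard reading of
  "within 1SD"); the summary reports the percentage of muscles inside
  each, plus the median/min/max of estimates normalised by the per-muscle
  reference median. Muscles with fewer than two reference values are
  excluded with a warning.
- **Regression**: OLS of estimates on reference means, with
  adjusted R² = 1 − (1−R²)(n−1)/(n−2).

## Synthetic fixtures

Tubes are swept along a parametric centerline with a radius profile:
rings at uniform parameter values, frames by parallel transport (no
twist), quad strips between rings, triangle-fan caps centred on the
centerline endpoints. Generation is fully deterministic. The generator
refuses radii exceeding the local curvature radius (self-intersection).
Ground truth includes the sampled centerline, cap centroids and cap face
selections (consistent with `attachment_centroid` to 1e-9), and the
analytic volume — πr²h for straight constant-radius tubes, otherwise the
composite-Simpson integral of πr(t)²|c'(t)| on 10001 samples.

What the fixtures do *not* emulate: pennation, fiber architecture,
multiple heads, wrapping around bones, and the irregular attachment
footprints of real muscles. Passing tests on these fixtures shows the
geometric operators are correct on closed meshes with known truth; it
does not validate anatomical fidelity of any particular reconstruction.

## Problem sizes and tolerances

Default test fixtures use 16–64 ring/side resolutions (256–512 sides
where an example's tolerance demands it), 1000-triangle random batches,
and 10⁶-sample Monte-Carlo centroid checks; exact enumeration for the
Mann–Whitney oracle runs over all sample-size pairs with max(n) ≤ 7.
Geometric identity checks use 1e-9 relative tolerances; discretisation
checks state their tolerance next to the analytic value they approach.
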