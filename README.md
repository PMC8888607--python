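# myoline

Volumetric muscle geometry for musculoskeletal modelling: attachment
centroids, automated line-of-action (LoA) estimation from closed polygonal
muscle meshes, muscle mass from mesh volume, and the agreement statistics
used to evaluate such estimates against dissection data.

It is aimed at biomechanists and comparative anatomists who build 3D
volumetric muscle reconstructions (from surface scans, diceCT/MRI
segmentations, or sculpted models of extinct taxa) and need to turn them
into the quantities musculoskeletal simulation software consumes: muscle
path points, muscle–tendon-unit (MTU) lengths, and masses.

## The method

**Attachment centroid.** An attachment area is a selection of mesh faces.
Each face is triangulated; a triangle with vertices A, B, C and side
lengths a = |BC|, b = |AC|, c = |AB| has semi-perimeter s = (a+b+c)/2,
Heron area

    w_i = sqrt(s (s−a) (s−b) (s−c)),

and centroid C_i = (A+B+C)/3. The attachment centroid is the area-weighted
mean C_A = Σ w_i C_i / W_A with W_A = Σ w_i.

**Line of action.** Given the origin and insertion centroids and the closed
belly mesh, the belly is cut by n evenly spaced planes perpendicular to the
origin→insertion axis (at interior parameters t_i = i/(n+1), so no plane
touches an attachment cap). Each planar cross-section — one or more closed
loops — gets an area-weighted centroid computed the same way, and the
centroids are threaded origin-first into the LoA path. The path can be
smoothed into a cubic spline with fixed endpoints; its arc length is the
MTU length; it exports to CSV, JSON, OBJ polylines, or OpenSim PathPoint
XML (metres).

**Mass.** Closed-mesh volume by the signed origin-tetrahedron sum, then
mass = volume × 1060 kg/m³ (homogeneous fresh muscle); an explicit
muscle/tendon partition can use 1120 kg/m³ for the tendon fraction.

**Evaluation.** Bland–Altman bias and limits of agreement, two-sided
Mann–Whitney U (exact for small tie-free samples), within-reference-range
summaries (mean±1SD, mean±2SD, [min,max], [min−20%, max+20%]), and OLS
regression with adjusted R². When a bias is reported as `bias ± h`, h is
the 95% CI half-width of the bias, not the limits of agreement.

Because scan-derived meshes are large and rarely redistributable, the
`synthetic` module generates closed muscle-like fixtures with analytic
ground truth — straight and curved constant/varying-radius tubes, and a
prism with an oblique attachment cap that reproduces the characteristic
LoA "kink" artifact near wide attachments angled to the slicing axis.

## Worked example

```sh
$ myoline synth tube --radius 1 --length 10 --rings 8 --sides 32 --out cyl.obj
wrote cyl.obj
$ myoline loa --mesh cyl.obj --origin-group origin --insertion-group insertion \
      --slices 10 --units cm --out loa.csv
LoA: 12 points, arc length 10 cm -> loa.csv
$ myoline mass --mesh cyl.obj --units cm
volume: 31.2144515 cm^3
mass:   0.033087 kg
```

The 12 CSV rows are the origin centroid, ten slice centroids, and the
insertion centroid — all on the cylinder axis, so the arc length equals
the 10 cm muscle length. The volume is the inscribed 32-gon tube's volume
(π·1²·10 ≈ 31.416 cm³ in the smooth limit), and the mass is volume ×
1060 kg/m³. The same workflow applies to real OBJ/STL/PLY muscle meshes,
with attachment areas given as face-selection files (`--origin-faces`) or
OBJ groups.

In Python:

```python
from myoline import read_mesh, attachment_centroid, estimate_loa, mass_from_volume
from myoline.mesh_core import read_face_selection, mesh_volume

mesh = read_mesh("muscle.obj", unit="cm")
origin = attachment_centroid(read_face_selection(mesh, "origin_faces.txt"))
insertion = attachment_centroid(read_face_selection(mesh, "insertion_faces.txt"))
path = estimate_loa(mesh, origin, insertion, n_slices=20)
mass_kg = mass_from_volume(mesh_volume(mesh), unit="cm")
```

## Layout

- `myoline.mesh_core` — mesh model, OBJ/STL/PLY I/O, triangulation, areas,
  signed-tetrahedron volume, topology checks
- `myoline.centroid` — Heron areas and area-weighted attachment centroids
- `myoline.loa` — slicing planes, cross-sections, LoA threading, smoothing,
  arc length, export
- `myoline.mass` — volume→mass at tissue densities, normalisations
- `myoline.evalstats` — Bland–Altman, Mann–Whitney U, range summaries, OLS
- `myoline.synthetic` — fixture generators with analytic ground truth
- `myoline.cli` — the `myoline` command

See `docs/methods.md` for the numerical and design details.
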