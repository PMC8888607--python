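"""Synthetic muscle-like meshes with known ground truth.

Real muscle meshes come from scans and sculpting; for testing, this module
generates closed fusiform/tubular bellies whose centerline, radii, volume,
and attachment-cap centroids are known analytically (or by numeric
integration of the tube integral ∫ π r(t)² |c'(t)| dt):

* :func:`make_tube` — a swept tube along an arbitrary centerline with a
  radius profile, built on parallel-transport frames (no twist), with
  triangle-fan end caps.
* :func:`make_primitive` — cube, icosphere, and cone/frustum primitives
  with exact reference volumes and areas.
* :func:`make_oblique_muscle` — a prism whose origin cap is tilted
  relative to the long axis: the geometry that produces the spurious
  "kink" in sliced line-of-action estimates, because near-cap slicing
  planes cut through the oblique attachment and their truncated sections
  pull the centroid toward the side the cap leans.

Generation is deterministic given the spec — there is no hidden randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh as _trimesh
from scipy.integrate import simpson

from .mesh_core import FaceSelection, PolyMesh, signed_volume

__all__ = [
    "TubeSpec",
    "GroundTruth",
    "make_tube",
    "make_primitive",
    "make_oblique_muscle",
    "straight_cylinder_spec",
    "quarter_torus_spec",
]


@dataclass
class TubeSpec:
    """Parametric description of a tubular muscle belly.

    ``centerline`` maps t ∈ [0, 1] to a 3D point; ``radius_profile`` maps t
    to a positive radius.  ``description`` tags analytically special cases
    ("straight-constant" enables the closed-form cylinder volume).
    """

    centerline: Callable[[float], np.ndarray]
    radius_profile: Callable[[float], float]
    n_rings: int = 32
    n_sides: int = 32
    capped: bool = True
    description: str = "generic"
    unit: str = "mm"
    name: str = "tube"

    def __post_init__(self):
        if self.n_rings < 2 or self.n_sides < 8:
            raise ValueError("need n_rings >= 2 and n_sides >= 8")


@dataclass
class GroundTruth:
    """Analytic/numeric truth accompanying a generated mesh."""

    centerline_samples: np.ndarray
    analytic_volume: float | None = None
    analytic_area: float | None = None
    cap_centroids: tuple | None = None
    cap_face_selections: tuple | None = None
    extras: dict = field(default_factory=dict)


def straight_cylinder_spec(radius: float, length: float, **kw) -> TubeSpec:
    """A straight constant-radius cylinder along +z."""
    return TubeSpec(
        centerline=lambda t: np.array([0.0, 0.0, t * length]),
        radius_profile=lambda t: radius,
        description="straight-constant",
        **kw,
    )


def quarter_torus_spec(arc_radius: float, tube_radius: float, **kw) -> TubeSpec:
    """A quarter-circle arc of radius ``arc_radius`` in the xy-plane swept
    with a constant tube radius."""
    def c(t):
        ang = t * math.pi / 2
        return np.array([arc_radius * math.cos(ang), arc_radius * math.sin(ang), 0.0])

    return TubeSpec(
        centerline=c,
        radius_profile=lambda t: tube_radius,
        description="quarter-torus",
        **kw,
    )


def _frames(points: np.ndarray):
    """Parallel-transport orthonormal frames along a sampled curve."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    t0 = tangents[0]
    helper = np.array([1.0, 0.0, 0.0]) if abs(t0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n = np.cross(t0, helper)
    n /= np.linalg.norm(n)
    normals = [n]
    for i in range(1, len(points)):
        n = normals[-1] - (normals[-1] @ tangents[i]) * tangents[i]
        norm = np.linalg.norm(n)
        if norm < 1e-12:  # tangent flipped ~180°; keep previous frame
            n = normals[-1]
        else:
            n = n / norm
        normals.append(n)
    normals = np.array(normals)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def _numeric_tube_volume(spec: TubeSpec, n: int = 10001) -> float:
    t = np.linspace(0.0, 1.0, n)
    pts = np.array([spec.centerline(ti) for ti in t])
    speed = np.linalg.norm(np.gradient(pts, t, axis=0), axis=1)
    r = np.array([spec.radius_profile(ti) for ti in t])
    return float(simpson(math.pi * r**2 * speed, x=t))


def _check_curvature(spec: TubeSpec, n: int = 512):
    t = np.linspace(0.0, 1.0, n)
    pts = np.array([spec.centerline(ti) for ti in t])
    d1 = np.gradient(pts, t, axis=0)
    d2 = np.gradient(d1, t, axis=0)
    speed = np.linalg.norm(d1, axis=1)
    kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(speed**3, 1e-300)
    r = np.array([spec.radius_profile(ti) for ti in t])
    if np.any(r * kappa >= 1.0):
        raise ValueError("radius exceeds curvature bound: tube would self-intersect")


def _orient_outward(vertices, faces, groups):
    mesh = PolyMesh(vertices, faces, groups=groups)
    if signed_volume(mesh) < 0:
        faces = [tuple(reversed(f)) for f in faces]
    return faces


def make_tube(spec: TubeSpec) -> tuple[PolyMesh, GroundTruth]:
    """Generate a swept-tube mesh and its ground truth.

    The tube is a quad strip between ``n_rings`` rings placed at uniform
    parameter values; when ``capped``, each end gets a triangle fan around
    a center vertex at the centerline endpoint, and the cap face selections
    plus centroids are recorded in the ground truth.
    """
    _check_curvature(spec)
    t = np.linspace(0.0, 1.0, spec.n_rings)
    centers = np.array([spec.centerline(ti) for ti in t])
    radii = np.array([spec.radius_profile(ti) for ti in t])
    if np.any(radii <= 0):
        raise ValueError("radius profile must be positive on [0, 1]")
    _, normals, binormals = _frames(centers)

    phi = np.linspace(0.0, 2.0 * math.pi, spec.n_sides, endpoint=False)
    vertices = []
    for i in range(spec.n_rings):
        ring = (
            centers[i]
            + radii[i] * (np.cos(phi)[:, None] * normals[i] + np.sin(phi)[:, None] * binormals[i])
        )
        vertices.extend(ring)
    vertices = np.array(vertices)

    def vid(i, j):
        return i * spec.n_sides + j % spec.n_sides

    faces = []
    for i in range(spec.n_rings - 1):
        for j in range(spec.n_sides):
            faces.append((vid(i, j), vid(i, j + 1), vid(i + 1, j + 1), vid(i + 1, j)))

    groups = {}
    cap_sel_idx = None
    if spec.capped:
        c0 = len(vertices)
        c1 = c0 + 1
        vertices = np.vstack([vertices, centers[0], centers[-1]])
        origin_cap = []
        for j in range(spec.n_sides):
            origin_cap.append(len(faces))
            faces.append((c0, vid(0, j + 1), vid(0, j)))
        insertion_cap = []
        last = spec.n_rings - 1
        for j in range(spec.n_sides):
            insertion_cap.append(len(faces))
            faces.append((c1, vid(last, j), vid(last, j + 1)))
        groups = {"origin": origin_cap, "insertion": insertion_cap}
        cap_sel_idx = (origin_cap, insertion_cap)

    faces = _orient_outward(vertices, faces, groups)
    mesh = PolyMesh(vertices, faces, name=spec.name, unit=spec.unit, groups=groups)

    if spec.description == "straight-constant":
        h = np.linalg.norm(centers[-1] - centers[0])
        analytic_volume = math.pi * radii[0] ** 2 * h
    else:
        analytic_volume = _numeric_tube_volume(spec)

    truth = GroundTruth(
        centerline_samples=centers,
        analytic_volume=analytic_volume,
        cap_centroids=(centers[0].copy(), centers[-1].copy()) if spec.capped else None,
        cap_face_selections=(
            (FaceSelection(mesh, cap_sel_idx[0]), FaceSelection(mesh, cap_sel_idx[1]))
            if spec.capped
            else None
        ),
        extras={"radii": radii},
    )
    return mesh, truth


def make_primitive(kind: str, **params) -> PolyMesh:
    """Primitives with exact reference measures: ``cube`` (edge), ``icosphere``
    (radius, subdivisions), ``frustum`` (r1, r2, h, n_sides; r2=0 is a cone)."""
    unit = params.pop("unit", "mm")
    if kind == "cube":
        e = float(params.pop("edge", 1.0))
        if e <= 0:
            raise ValueError("cube edge must be positive")
        v = np.array(
            [[0, 0, 0], [e, 0, 0], [e, e, 0], [0, e, 0], [0, 0, e], [e, 0, e], [e, e, e], [0, e, e]],
            dtype=float,
        )
        f = [
            (0, 3, 2, 1),  # bottom (z=0, outward -z)
            (4, 5, 6, 7),  # top
            (0, 1, 5, 4),  # y=0
            (2, 3, 7, 6),  # y=e
            (1, 2, 6, 5),  # x=e
            (3, 0, 4, 7),  # x=0
        ]
        return PolyMesh(v, f, name="cube", unit=unit)
    if kind == "icosphere":
        radius = float(params.pop("radius", 1.0))
        subdivisions = int(params.pop("subdivisions", 3))
        if radius <= 0 or subdivisions < 0 or subdivisions > 6:
            raise ValueError("invalid icosphere parameters")
        tm = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return PolyMesh(np.asarray(tm.vertices), [tuple(f) for f in tm.faces],
                        name="icosphere", unit=unit)
    if kind == "frustum":
        r1 = float(params.pop("r1", 1.0))
        r2 = float(params.pop("r2", 0.5))
        h = float(params.pop("h", 1.0))
        n = int(params.pop("n_sides", 64))
        if r1 <= 0 or r2 < 0 or h <= 0 or n < 8:
            raise ValueError("invalid frustum parameters")
        phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
        ring1 = np.column_stack([r1 * np.cos(phi), r1 * np.sin(phi), np.zeros(n)])
        faces = []
        if r2 > 0:
            ring2 = np.column_stack([r2 * np.cos(phi), r2 * np.sin(phi), np.full(n, h)])
            v = np.vstack([ring1, ring2, [[0, 0, 0]], [[0, 0, h]]])
            b0, b1 = 2 * n, 2 * n + 1
            for j in range(n):
                jn = (j + 1) % n
                faces.append((j, jn, n + jn, n + j))
                faces.append((b0, jn, j))
                faces.append((b1, n + j, n + jn))
        else:
            v = np.vstack([ring1, [[0, 0, h]], [[0, 0, 0]]])
            apex, base = n, n + 1
            for j in range(n):
                jn = (j + 1) % n
                faces.append((apex, j, jn))
                faces.append((base, jn, j))
        faces = _orient_outward(v, faces, {})
        return PolyMesh(v, faces, name="frustum", unit=unit)
    raise ValueError(f"unknown primitive kind {kind!r}")


def make_oblique_muscle(
    length: float,
    width: float,
    thickness: float,
    cap_angle: float,
    unit: str = "mm",
) -> tuple[PolyMesh, GroundTruth]:
    """A prism whose origin cap is tilted ``cap_angle`` degrees about the
    width axis — the oblique, sheet-like attachment geometry that produces
    the line-of-action kink artifact.

    The cap pivots about its own centroid, so the origin centroid stays at
    the coordinate origin and the true long axis is the +x chord to the
    insertion centroid at (length, 0, 0).  The prism volume is preserved
    (= length × width × thickness) because the tilt shifts material
    symmetrically about the mid-thickness plane.
    """
    if not (0 <= cap_angle < 80):
        raise ValueError("cap_angle must be in [0, 80) degrees")
    if min(length, width, thickness) <= 0:
        raise ValueError("dimensions must be positive")
    tn = math.tan(math.radians(cap_angle))
    if thickness / 2 * tn >= length:
        raise ValueError("cap tilt exceeds prism length")
    w2, t2 = width / 2.0, thickness / 2.0
    v = np.array(
        [
            [-t2 * tn, -w2, -t2],
            [-t2 * tn, w2, -t2],
            [t2 * tn, w2, t2],
            [t2 * tn, -w2, t2],
            [length, -w2, -t2],
            [length, w2, -t2],
            [length, w2, t2],
            [length, -w2, t2],
        ]
    )
    faces = [
        (0, 1, 2, 3),  # origin cap (tilted)
        (4, 7, 6, 5),  # insertion cap
        (0, 4, 5, 1),  # bottom z=-t2
        (3, 2, 6, 7),  # top z=+t2
        (0, 3, 7, 4),  # side y=-w2
        (1, 5, 6, 2),  # side y=+w2
    ]
    groups = {"origin": [0], "insertion": [1]}
    faces = _orient_outward(v, faces, groups)
    mesh = PolyMesh(v, faces, name="oblique_muscle", unit=unit, groups=groups)
    truth = GroundTruth(
        centerline_samples=np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]]),
        analytic_volume=length * width * thickness,
        cap_centroids=(np.zeros(3), np.array([length, 0.0, 0.0])),
        cap_face_selections=(FaceSelection(mesh, [0]), FaceSelection(mesh, [1])),
        extras={"cap_angle_deg": cap_angle, "tan_cap_angle": tn},
    )
    return mesh, truth
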