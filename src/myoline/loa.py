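"""Muscle line-of-action (LoA) estimation by cross-section slicing.

A muscle's LoA is estimated from its closed belly mesh and the centroids of
its two attachments: the belly is sliced by a user-specified number of
planes perpendicular to the origin→insertion axis, the area-weighted
centroid of each planar cross-section is computed, and the centroids are
threaded — origin centroid first, insertion centroid last — into an ordered
path.  The path can be smoothed into a spline curve, measured (arc length =
muscle–tendon-unit length), and exported for musculoskeletal modelling
software (CSV, JSON, OBJ polyline, or OpenSim PathPoint XML).

Slicing planes are placed at the interior parameters t_i = i/(n+1) of the
origin→insertion segment so that no plane coincides with an attachment cap.

When a slice intersects the mesh in several disjoint loops (e.g. near a
wide attachment angled to the axis), the loops are combined by area
weighting by default.  This deliberately reproduces the characteristic
"kink" artifact near oblique sheet-like attachments, where attachment-area
material entering the slice drags the centroid sideways; passing
``nearest_loop=True`` instead keeps only the loop closest to the axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
from scipy.interpolate import splev, splprep
from shapely.geometry import Polygon as _ShapelyPolygon

from .centroid import AttachmentCentroid
from .mesh_core import UNIT_TO_M, Plane, PolyMesh, triangulate

__all__ = [
    "AttachmentPair",
    "CrossSection",
    "LineOfAction",
    "slice_planes",
    "cross_section",
    "section_centroid",
    "estimate_loa",
    "smooth_loa",
    "arc_length",
    "export_loa",
    "read_loa_csv",
]


@dataclass(frozen=True)
class AttachmentPair:
    """Origin and insertion centroid positions defining the slicing axis."""

    origin: np.ndarray
    insertion: np.ndarray

    def __init__(self, origin, insertion):
        origin = np.asarray(origin, dtype=float)
        insertion = np.asarray(insertion, dtype=float)
        if np.linalg.norm(insertion - origin) == 0:
            raise ValueError("degenerate axis: origin equals insertion")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "insertion", insertion)

    @property
    def axis(self) -> np.ndarray:
        d = self.insertion - self.origin
        return d / np.linalg.norm(d)


@dataclass
class CrossSection:
    """Planar cut through a closed mesh: one or more closed loops."""

    plane: Plane
    loops: list  # each an (k, 3) array, first point repeated last
    area: float
    centroid: np.ndarray | None

    @property
    def n_loops(self) -> int:
        return len(self.loops)


@dataclass
class LineOfAction:
    """Ordered path from origin centroid through slice centroids to insertion."""

    points: np.ndarray  # (m, 3)
    unit: str = "mm"
    smoothed: np.ndarray | None = None
    skipped_slices: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a line of action needs at least 2 points of dimension 3")

    @property
    def arc_length(self) -> float:
        return arc_length(self)


def slice_planes(pair: AttachmentPair, n_slices: int) -> list[Plane]:
    """Evenly spaced planes at the interior parameters of the attachment axis.

    Plane i (1-based) passes through origin + i/(n+1)·(insertion − origin)
    with normal along the axis, so the attachment caps themselves are never
    sliced.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    axis = pair.axis
    seg = pair.insertion - pair.origin
    return [
        Plane(pair.origin + (i / (n_slices + 1)) * seg, axis)
        for i in range(1, n_slices + 1)
    ]


def _loop_area_centroid(loop3d: np.ndarray, plane: Plane):
    """Planar area and 3D centroid of a closed loop via its 2D projection."""
    u, v = plane.basis()
    rel = loop3d - plane.point
    pts2d = np.column_stack([rel @ u, rel @ v])
    poly = _ShapelyPolygon(pts2d)
    if not poly.is_valid:
        poly = poly.buffer(0)
    area = poly.area
    if area <= 0:
        return 0.0, None
    c = poly.centroid
    centroid3d = plane.point + c.x * u + c.y * v
    return float(area), centroid3d


def cross_section(mesh: PolyMesh, plane: Plane, tol_rel: float = 1e-9) -> CrossSection:
    """Intersect a closed mesh with a plane and chain the cut into loops.

    Each triangle straddling the plane contributes one segment; segments are
    chained into closed loops by matching endpoints within
    ``tol_rel × bbox diagonal``.  A plane passing exactly through vertices is
    perturbed along its normal by the same tolerance (deterministically)
    so every crossing is transversal.
    """
    bbox = mesh.bbox_diagonal
    tol = tol_rel * bbox if bbox > 0 else tol_rel
    tris = triangulate(mesh)
    V = mesh.vertices
    d = plane.signed_distance(V)
    if np.any(np.abs(d) < tol):
        # symbolic-style perturbation: shift the plane offset slightly
        plane = Plane(plane.point + 1e-9 * bbox * plane.normal, plane.normal)
        d = plane.signed_distance(V)

    segments = []
    td = d[tris]  # (m, 3) signed distances per triangle vertex
    crossing = ~(np.all(td > 0, axis=1) | np.all(td < 0, axis=1))
    for t, dist in zip(tris[crossing], td[crossing]):
        pts = []
        for i in range(3):
            a, b = t[i], t[(i + 1) % 3]
            da, db = dist[i], dist[(i + 1) % 3]
            if (da > 0) != (db > 0):
                w = da / (da - db)
                pts.append(V[a] + w * (V[b] - V[a]))
        if len(pts) == 2:
            segments.append(pts)
    if not segments:
        return CrossSection(plane=plane, loops=[], area=0.0, centroid=None)

    # merge segment endpoints within tolerance into graph nodes
    endpoints = np.array([p for seg in segments for p in seg])
    from scipy.spatial import cKDTree

    tree = cKDTree(endpoints)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(endpoints))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(endpoints))])
    _, node_ids = np.unique(roots, return_inverse=True)
    n_nodes = node_ids.max() + 1
    node_pos = np.zeros((n_nodes, 3))
    counts = np.bincount(node_ids)
    np.add.at(node_pos, node_ids, endpoints)
    node_pos /= counts[:, None]

    # adjacency from segments; drop zero-length segments
    adj = {i: set() for i in range(n_nodes)}
    for k in range(len(segments)):
        a, b = node_ids[2 * k], node_ids[2 * k + 1]
        if a != b:
            adj[a].add(b)
            adj[b].add(a)

    loops = []
    visited_edges = set()
    for start in range(n_nodes):
        for nxt in adj[start]:
            if (start, nxt) in visited_edges:
                continue
            path = [start]
            prev, cur = start, nxt
            visited_edges.add((start, nxt))
            visited_edges.add((nxt, start))
            while cur != start:
                path.append(cur)
                candidates = [n for n in adj[cur] if n != prev]
                if not candidates:
                    raise ValueError(
                        "open intersection chain on a closed mesh; "
                        "loop-chaining tolerance failed"
                    )
                nxt2 = candidates[0]
                visited_edges.add((cur, nxt2))
                visited_edges.add((nxt2, cur))
                prev, cur = cur, nxt2
            if len(path) >= 3:
                loop = node_pos[path]
                loops.append(np.vstack([loop, loop[:1]]))

    total_area = 0.0
    weighted = np.zeros(3)
    kept = []
    for loop in loops:
        area, c = _loop_area_centroid(loop, plane)
        if c is None:
            continue
        kept.append(loop)
        total_area += area
        weighted += area * c
    centroid = weighted / total_area if total_area > 0 else None
    return CrossSection(plane=plane, loops=kept, area=float(total_area), centroid=centroid)


def section_centroid(section: CrossSection) -> np.ndarray:
    """Area-weighted centroid over all loops of a cross-section.

    Each loop's planar centroid (valid for non-convex outlines) is weighted
    by its area; disjoint loops combine exactly like triangles do in the
    attachment-centroid computation.
    """
    if section.n_loops == 0 or section.area <= 0 or section.centroid is None:
        raise ValueError("cross-section has no loop with positive area")
    return section.centroid


def _as_point(x) -> np.ndarray:
    if isinstance(x, AttachmentCentroid):
        return x.centroid
    return np.asarray(x, dtype=float)


def estimate_loa(
    mesh: PolyMesh,
    origin,
    insertion,
    n_slices: int,
    nearest_loop: bool = False,
) -> LineOfAction:
    """Estimate a muscle's line of action.

    Parameters
    ----------
    mesh : PolyMesh
        Closed muscle belly mesh.
    origin, insertion : AttachmentCentroid or (3,) point
        Attachment centroids anchoring the path ends and the slicing axis.
    n_slices : int
        Number of cross-sections between the attachments.
    nearest_loop : bool
        When a slice yields several disjoint loops, keep only the loop
        closest to the origin–insertion chord instead of area-weighting
        them all (suppresses the oblique-attachment kink artifact).

    Returns
    -------
    LineOfAction
        points = [origin centroid, slice centroids in axis order,
        insertion centroid].  Empty slices are skipped with a warning; if
        more than half are empty the axis is assumed to miss the muscle.
    """
    o = _as_point(origin)
    i = _as_point(insertion)
    pair = AttachmentPair(o, i)
    planes = slice_planes(pair, n_slices)
    pts = [o]
    skipped = 0
    for plane in planes:
        sec = cross_section(mesh, plane)
        if sec.n_loops == 0 or sec.area <= 0:
            skipped += 1
            continue
        if nearest_loop and sec.n_loops > 1:
            best, best_d = None, np.inf
            for loop in sec.loops:
                area, c = _loop_area_centroid(loop, plane)
                if c is None:
                    continue
                # distance from loop centroid to the origin-insertion chord
                w = c - o
                d = np.linalg.norm(w - (w @ pair.axis) * pair.axis)
                if d < best_d:
                    best, best_d = c, d
            pts.append(best)
        else:
            pts.append(section_centroid(sec))
    if skipped > n_slices / 2:
        raise ValueError(
            f"axis misses muscle: {skipped} of {n_slices} slices were empty"
        )
    if skipped:
        warnings.warn(f"skipped {skipped} empty slice(s)", stacklevel=2)
    pts.append(i)
    return LineOfAction(points=np.array(pts), unit=mesh.unit, skipped_slices=skipped)


def smooth_loa(loa: LineOfAction, n_samples: int = 100, smoothing: float = 0.0) -> LineOfAction:
    """Fit a cubic spline through the path and resample it.

    ``smoothing=0`` interpolates every point; larger values trade closeness
    for smoothness.  The first and last points (the attachment centroids)
    are always preserved exactly.  Paths with fewer than 4 points fall back
    to linear resampling.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    pts = loa.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    if u[-1] == 0:
        raise ValueError("degenerate path: zero total length")
    u /= u[-1]
    us = np.linspace(0.0, 1.0, n_samples)
    if len(pts) < 4:
        smooth = np.column_stack([np.interp(us, u, pts[:, k]) for k in range(3)])
    else:
        # heavy endpoint weights pin the curve to the attachment centroids
        w = np.ones(len(pts))
        w[0] = w[-1] = 1e6
        tck, _ = splprep(pts.T, u=u, w=w, s=smoothing, k=3)
        smooth = np.column_stack(splev(us, tck))
    smooth[0] = pts[0]
    smooth[-1] = pts[-1]
    return LineOfAction(
        points=pts, unit=loa.unit, smoothed=smooth, skipped_slices=loa.skipped_slices
    )


def arc_length(loa: LineOfAction, use_smoothed: bool = False) -> float:
    """Polyline length of the raw path or its smoothed curve (MTU length)."""
    pts = loa.smoothed if use_smoothed else loa.points
    if pts is None:
        raise ValueError("no smoothed curve available; call smooth_loa first")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def export_loa(loa: LineOfAction, format: str, path) -> str:
    """Write an LoA as ``csv``, ``json``, ``obj_polyline``, or
    ``osim_pathpoints`` (OpenSim PathPoint XML, coordinates in metres)."""
    pts = loa.points
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("x,y,z\n")
            for p in pts:
                fh.write(f"{p[0]:.12g},{p[1]:.12g},{p[2]:.12g}\n")
    elif format == "json":
        payload = {
            "unit": loa.unit,
            "n_points": int(len(pts)),
            "arc_length": arc_length(loa),
            "skipped_slices": loa.skipped_slices,
            "points": pts.tolist(),
        }
        if loa.smoothed is not None:
            payload["smoothed"] = loa.smoothed.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif format == "obj_polyline":
        with open(path, "w") as fh:
            fh.write(f"# line of action (unit: {loa.unit})\n")
            for p in pts:
                fh.write(f"v {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            fh.write("l " + " ".join(str(i + 1) for i in range(len(pts))) + "\n")
    elif format == "osim_pathpoints":
        scale = UNIT_TO_M[loa.unit]
        root = ET.Element("PathPointSet")
        objects = ET.SubElement(root, "objects")
        for k, p in enumerate(pts, start=1):
            pp = ET.SubElement(objects, "PathPoint", name=f"p{k}")
            loc = ET.SubElement(pp, "location")
            loc.text = f"{p[0] * scale:.12g} {p[1] * scale:.12g} {p[2] * scale:.12g}"
        ET.indent(root)
        ET.ElementTree(root).write(path, encoding="unicode")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return str(path)


def read_loa_csv(path, unit: str = "mm") -> LineOfAction:
    """Read back a CSV written by :func:`export_loa`."""
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return LineOfAction(points=pts, unit=unit)
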