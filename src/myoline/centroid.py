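"""Area-weighted attachment centroids.

The attachment centroid of a muscle is the area-weighted mean of the
centroids of the triangles tiling its attachment area:

* triangle side lengths a = |BC|, b = |AC|, c = |AB| give the
  semi-perimeter s = (a + b + c) / 2,
* each triangle's area is Heron's w_i = sqrt(s(s-a)(s-b)(s-c)),
* each triangle's centroid is C_i = (A + B + C) / 3,
* the attachment centroid is C_A = Σ w_i C_i / W_A with W_A = Σ w_i.

This is the extrinsic (3D-embedded) area-weighted mean; for strongly
curved patches it can lie off the surface, which is intentional — the
centroid anchors a line of action, not a surface landmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh_core import FaceSelection, triangulate

__all__ = [
    "Triangle",
    "WeightedTriangle",
    "AttachmentCentroid",
    "heron_area",
    "triangle_centroid",
    "area_weighted_centroid",
    "attachment_centroid",
]

#: triangles with area below this fraction of the largest are treated as zero
RELATIVE_AREA_FLOOR = 1e-12


@dataclass(frozen=True)
class Triangle:
    """A 3D triangle with vertices A, B, C."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __init__(self, A, B, C):
        object.__setattr__(self, "A", np.asarray(A, dtype=float))
        object.__setattr__(self, "B", np.asarray(B, dtype=float))
        object.__setattr__(self, "C", np.asarray(C, dtype=float))

    @property
    def a(self) -> float:
        """|BC|"""
        return float(np.linalg.norm(self.C - self.B))

    @property
    def b(self) -> float:
        """|AC|"""
        return float(np.linalg.norm(self.C - self.A))

    @property
    def c(self) -> float:
        """|AB|"""
        return float(np.linalg.norm(self.B - self.A))


@dataclass(frozen=True)
class WeightedTriangle:
    """A triangle reduced to its centroid and area weight."""

    centroid: np.ndarray
    area: float

    def __init__(self, centroid, area):
        if area < 0:
            raise ValueError("triangle area weight must be >= 0")
        object.__setattr__(self, "centroid", np.asarray(centroid, dtype=float))
        object.__setattr__(self, "area", float(area))


@dataclass(frozen=True)
class AttachmentCentroid:
    """Result of the area-weighted centroid computation."""

    centroid: np.ndarray
    total_area: float
    n_vertices: int


def heron_area(tri: Triangle) -> float:
    """Triangle area from side lengths via Heron's formula.

    Near-degenerate triangles can push the radicand slightly negative in
    floating point; it is clamped to zero.
    """
    a, b, c = tri.a, tri.b, tri.c
    s = (a + b + c) / 2.0
    radicand = s * (s - a) * (s - b) * (s - c)
    return math.sqrt(max(radicand, 0.0))


def triangle_centroid(tri: Triangle) -> np.ndarray:
    """Centroid as the vertex average (A + B + C) / 3."""
    return (tri.A + tri.B + tri.C) / 3.0


def _heron_areas(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    # vectorised Heron over triangle vertex arrays
    a = np.linalg.norm(p2 - p1, axis=1)
    b = np.linalg.norm(p2 - p0, axis=1)
    c = np.linalg.norm(p1 - p0, axis=1)
    s = (a + b + c) / 2.0
    return np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None))


def area_weighted_centroid(tris: list[WeightedTriangle], n_vertices: int | None = None) -> AttachmentCentroid:
    """Combine weighted triangles into C_A = Σ w_i C_i / Σ w_i.

    ``n_vertices`` defaults to len(tris) + 2, the vertex count of a
    triangulated simple polygon; callers with the true selection vertex
    count pass it explicitly.
    """
    if not tris:
        raise ValueError("no triangles given")
    areas = np.array([t.area for t in tris])
    centroids = np.array([t.centroid for t in tris])
    areas[areas < RELATIVE_AREA_FLOOR * areas.max()] = 0.0 if areas.max() > 0 else 0.0
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate attachment: total area is zero")
    c = (areas[:, None] * centroids).sum(axis=0) / total
    return AttachmentCentroid(
        centroid=c,
        total_area=float(total),
        n_vertices=len(tris) + 2 if n_vertices is None else int(n_vertices),
    )


def attachment_centroid(selection: FaceSelection) -> AttachmentCentroid:
    """Area-weighted centroid of a selected attachment area.

    Triangulates the selected faces, computes per-triangle Heron areas and
    vertex-average centroids, and returns their area-weighted mean.  The
    result is independent of face ordering and of how many faces tile a
    given planar patch.
    """
    mesh = selection.mesh
    tris = triangulate(mesh, selection)
    if len(tris) == 0:
        raise ValueError("degenerate attachment: selection has no non-degenerate faces")
    p0, p1, p2 = (mesh.vertices[tris[:, i]] for i in range(3))
    areas = _heron_areas(p0, p1, p2)
    areas[areas < RELATIVE_AREA_FLOOR * areas.max()] = 0.0
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate attachment: total area is zero")
    centroids = (p0 + p1 + p2) / 3.0
    c = (areas[:, None] * centroids).sum(axis=0) / total
    return AttachmentCentroid(centroid=c, total_area=float(total), n_vertices=selection.n_vertices)
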