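"""Polygonal mesh data model, file I/O, and basic geometric measures.

Muscle and bone surfaces are represented as :class:`PolyMesh` — an ordered
vertex array plus ordered polygonal faces (triangles, quads, or general
k-gons, counter-clockwise when viewed from outside).  Attachment areas are
subsets of faces (:class:`FaceSelection`).  Everything downstream — the
attachment-centroid computation, cross-section slicing, and volume/mass
estimation — operates on these two types.

Conventions
-----------
* Internal face indexing is 0-based; Wavefront OBJ I/O converts to/from
  the format's 1-based indices.
* Each mesh carries a length-unit tag (``mm``, ``cm`` or ``m``) so that
  volumes can be converted to m³ before mass computation.
* Closed-mesh volume uses the signed origin-tetrahedron sum over the
  triangulated faces; an inward-wound mesh yields a negative signed sum,
  which is reported (``MeshReport.negative_volume_flag``) and corrected by
  absolute value.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "UNIT_TO_M",
    "PolyMesh",
    "FaceSelection",
    "Plane",
    "MeshReport",
    "MeshFormatError",
    "MeshTopologyError",
    "read_mesh",
    "write_mesh",
    "read_face_selection",
    "triangulate",
    "triangle_areas",
    "surface_area",
    "mesh_volume",
    "signed_volume",
    "validate_mesh",
    "weld_vertices",
]

#: metres per model unit, used when converting volumes to m³ for mass.
UNIT_TO_M = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}

#: relative (to squared bbox diagonal) area below which a face counts as degenerate
DEGENERATE_AREA_REL = 1e-12


class MeshFormatError(ValueError):
    """A mesh file violates its declared format."""


class MeshTopologyError(ValueError):
    """A mesh's connectivity is unsuitable for the requested operation."""


@dataclass
class PolyMesh:
    """A named polygonal surface mesh with a length-unit tag.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in model units.
    faces : sequence of index tuples
        Each face is an ordered tuple of ≥3 vertex indices,
        counter-clockwise when viewed from outside the surface.
    name : str
        Label, e.g. the muscle name.
    unit : {"mm", "cm", "m"}
        Length unit of the coordinates.
    groups : dict
        Optional named face groups (from OBJ ``g`` records), usable as
        attachment-area selections.
    """

    vertices: np.ndarray
    faces: list
    name: str = ""
    unit: str = "mm"
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if self.unit not in UNIT_TO_M:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(UNIT_TO_M)}")
        nv = len(self.vertices)
        faces = []
        for fi, f in enumerate(self.faces):
            f = tuple(int(i) for i in f)
            if len(f) < 3:
                raise MeshFormatError(f"face {fi} has fewer than 3 vertices")
            if len(set(f)) != len(f):
                raise MeshFormatError(f"face {fi} repeats a vertex index")
            if min(f) < 0 or max(f) >= nv:
                raise MeshFormatError(f"face {fi} references vertex index out of range [0, {nv})")
            faces.append(f)
        self.faces = faces

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bbox_diagonal(self) -> float:
        """Length of the axis-aligned bounding-box diagonal."""
        if self.n_vertices == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def select(self, face_indices) -> "FaceSelection":
        return FaceSelection(self, face_indices)

    def select_group(self, name: str) -> "FaceSelection":
        if name not in self.groups:
            raise KeyError(f"mesh has no face group named {name!r}")
        return FaceSelection(self, self.groups[name])


@dataclass(frozen=True)
class FaceSelection:
    """A non-empty subset of a mesh's faces marking an attachment area."""

    mesh: PolyMesh
    face_indices: tuple

    def __init__(self, mesh: PolyMesh, face_indices):
        idx = tuple(sorted({int(i) for i in face_indices}))
        if not idx:
            raise ValueError("face selection is empty")
        if idx[0] < 0 or idx[-1] >= mesh.n_faces:
            raise ValueError("face selection index out of range")
        object.__setattr__(self, "mesh", mesh)
        object.__setattr__(self, "face_indices", idx)

    def __len__(self):
        return len(self.face_indices)

    @property
    def n_vertices(self) -> int:
        """Number of distinct vertices describing the attachment area."""
        verts = set()
        for fi in self.face_indices:
            verts.update(self.mesh.faces[fi])
        return len(verts)


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __init__(self, point, normal):
        point = np.asarray(point, dtype=float)
        normal = np.asarray(normal, dtype=float)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "normal", normal / norm)

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.point @ self.normal

    def basis(self):
        """Return an orthonormal in-plane basis (u, v) with u × v = normal."""
        n = self.normal
        helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class MeshReport:
    """Topology/orientation diagnostics from :func:`validate_mesh`."""

    closed: bool
    boundary_edge_count: int
    non_manifold_edge_count: int
    negative_volume_flag: bool = False


# ---------------------------------------------------------------------------
# file I/O


def _detect_format(path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = Path(path).suffix.lower().lstrip(".")
    if ext in ("obj", "stl", "ply"):
        return ext
    raise MeshFormatError(f"cannot infer mesh format from {path!r}")


def _read_obj(path, unit: str, name: str) -> PolyMesh:
    vertices, faces, groups = [], [], {}
    current_group = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "g" and len(parts) > 1:
                current_group = parts[1]
                groups.setdefault(current_group, [])
            elif parts[0] == "f":
                idx = []
                for tok in parts[1:]:
                    i = int(tok.split("/")[0])
                    # OBJ is 1-based; negative indices count back from the end
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                for i in idx:
                    if i < 0 or i >= len(vertices):
                        raise MeshFormatError(
                            f"{path}: face at line {lineno} references vertex {i + 1} "
                            f"of {len(vertices)}"
                        )
                if current_group is not None:
                    groups[current_group].append(len(faces))
                faces.append(tuple(idx))
    if not vertices or not faces:
        raise MeshFormatError(f"{path}: empty mesh")
    groups = {k: v for k, v in groups.items() if v}
    return PolyMesh(np.array(vertices), faces, name=name, unit=unit, groups=groups)


def _read_ply(path, unit: str, name: str) -> PolyMesh:
    # ASCII PLY only; keeps polygonal faces intact.
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            header.append(line)
            if line == "end_header":
                break
            if not line:
                raise MeshFormatError(f"{path}: truncated PLY header")
        if "format ascii 1.0" not in header:
            raise MeshFormatError(f"{path}: only ASCII PLY is supported")
        n_vert = n_face = 0
        for line in header:
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
        body = fh.read().decode("ascii").split("\n")
    rows = [r.split() for r in body if r.strip()]
    if len(rows) < n_vert + n_face:
        raise MeshFormatError(f"{path}: PLY body shorter than declared")
    vertices = np.array([[float(x) for x in r[:3]] for r in rows[:n_vert]])
    faces = []
    for r in rows[n_vert : n_vert + n_face]:
        k = int(r[0])
        faces.append(tuple(int(i) for i in r[1 : 1 + k]))
    if n_vert == 0 or n_face == 0:
        raise MeshFormatError(f"{path}: empty mesh")
    return PolyMesh(vertices, faces, name=name, unit=unit)


def weld_vertices(vertices: np.ndarray, faces, tol: float = 1e-9):
    """Merge vertices closer than ``tol`` (coordinates rounded to the tol grid)."""
    keys = np.round(np.asarray(vertices, dtype=float) / tol)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    new_vertices = np.asarray(vertices)[np.sort(first)]
    # remap through the sorted-first ordering so vertex order is stable
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    remap = rank[inverse]
    new_faces = [tuple(int(remap[i]) for i in f) for f in faces]
    return new_vertices, new_faces


def _read_stl(path, unit: str, name: str, weld_tol: float) -> PolyMesh:
    tm = _trimesh.load(str(path), file_type="stl", process=False)
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path}: empty or unreadable STL")
    vertices, faces = weld_vertices(np.asarray(tm.vertices), [tuple(f) for f in tm.faces], weld_tol)
    return PolyMesh(vertices, faces, name=name, unit=unit)


def read_mesh(path, format: str = "auto", unit: str = "mm", weld_tol: float = 1e-9) -> PolyMesh:
    """Read an OBJ, STL, or PLY mesh.

    OBJ and ASCII-PLY faces are kept polygonal (not pre-triangulated) and
    OBJ ``g`` groups become named face selections; STL yields triangles with
    duplicate facet vertices welded at ``weld_tol``.
    """
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    fmt = _detect_format(path, format)
    name = Path(path).stem
    if fmt == "obj":
        return _read_obj(path, unit, name)
    if fmt == "ply":
        return _read_ply(path, unit, name)
    if fmt == "stl":
        return _read_stl(path, unit, name, weld_tol)
    raise MeshFormatError(f"unknown mesh format {fmt!r}")


def write_mesh(mesh: PolyMesh, path, format: str = "auto"):
    """Write a mesh as OBJ (1-based, polygonal), ASCII PLY, or STL (triangulated)."""
    fmt = _detect_format(path, format)
    if fmt == "obj":
        with open(path, "w") as fh:
            fh.write(f"# {mesh.name or 'mesh'} (unit: {mesh.unit})\n")
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
            face_to_group = {}
            for gname, fids in mesh.groups.items():
                for fi in fids:
                    face_to_group[fi] = gname
            current = None
            for fi, f in enumerate(mesh.faces):
                g = face_to_group.get(fi)
                if g != current:
                    fh.write(f"g {g if g is not None else 'default'}\n")
                    current = g
                fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
            for f in mesh.faces:
                fh.write(f"{len(f)} " + " ".join(str(i) for i in f) + "\n")
    elif fmt == "stl":
        tris = triangulate(mesh)
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=tris, process=False)
        tm.export(str(path))
    else:
        raise MeshFormatError(f"unknown mesh format {fmt!r}")
    return path


def read_face_selection(mesh: PolyMesh, path) -> FaceSelection:
    """Read a face selection file: one 0-based index or inclusive range ``a-b``
    per line; ``#`` starts a comment."""
    indices = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "-" in line[1:]:  # allow a leading minus to fail loudly below
                a, b = line.split("-", 1)
                indices.extend(range(int(a), int(b) + 1))
            else:
                indices.append(int(line))
    return FaceSelection(mesh, indices)


# ---------------------------------------------------------------------------
# triangulation and measures


def triangulate(mesh: PolyMesh, faces: FaceSelection | None = None) -> np.ndarray:
    """Triangulate polygonal faces into an (m, 3) index array.

    Quads are split along the (v0, v2) diagonal; k-gons with k > 4 are
    fan-triangulated from v0, preserving the parent face's orientation.
    Degenerate (collinear) faces are excluded with a warning.
    """
    face_list = mesh.faces if faces is None else [mesh.faces[i] for i in faces.face_indices]
    tris = []
    degenerate = []
    area_tol = DEGENERATE_AREA_REL * mesh.bbox_diagonal**2
    V = mesh.vertices
    for f in face_list:
        cand = [(f[0], f[i], f[i + 1]) for i in range(1, len(f) - 1)]
        p0 = V[[t[0] for t in cand]]
        p1 = V[[t[1] for t in cand]]
        p2 = V[[t[2] for t in cand]]
        areas = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
        if areas.sum() <= area_tol:
            degenerate.append(f)
            continue
        tris.extend(cand)
    if degenerate:
        warnings.warn(
            f"excluded {len(degenerate)} degenerate (zero-area) face(s) from triangulation",
            stacklevel=2,
        )
    return np.array(tris, dtype=int).reshape(-1, 3)


def triangle_areas(vertices: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Areas of index triangles via the cross-product formula."""
    p0, p1, p2 = (vertices[tris[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)


def surface_area(selection: FaceSelection) -> float:
    """Total area of the selected faces (the W_A of the attachment-centroid
    computation), summed over their triangulation."""
    tris = triangulate(selection.mesh, selection)
    if len(tris) == 0:
        raise ValueError("selection triangulates to nothing (degenerate faces only)")
    return float(triangle_areas(selection.mesh.vertices, tris).sum())


def _edge_counts(mesh: PolyMesh):
    counts = {}
    for f in mesh.faces:
        for i in range(len(f)):
            e = (f[i], f[(i + 1) % len(f)])
            key = (min(e), max(e))
            counts[key] = counts.get(key, 0) + 1
    return counts


def validate_mesh(mesh: PolyMesh) -> MeshReport:
    """Report boundary edges (used by exactly one face), non-manifold edges
    (used by more than two), and winding orientation of a closed mesh."""
    counts = _edge_counts(mesh)
    boundary = sum(1 for c in counts.values() if c == 1)
    non_manifold = sum(1 for c in counts.values() if c > 2)
    closed = boundary == 0
    negative = False
    if closed and non_manifold == 0:
        negative = signed_volume(mesh) < 0
    return MeshReport(
        closed=closed,
        boundary_edge_count=boundary,
        non_manifold_edge_count=non_manifold,
        negative_volume_flag=negative,
    )


def signed_volume(mesh: PolyMesh) -> float:
    """Signed origin-tetrahedron volume sum over the triangulated faces.

    Positive for a closed mesh with outward-facing (counter-clockwise)
    winding; the magnitude is the enclosed volume regardless of the mesh's
    position relative to the origin.
    """
    tris = triangulate(mesh)
    p0, p1, p2 = (mesh.vertices[tris[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)


def mesh_volume(mesh: PolyMesh) -> float:
    """Enclosed volume of a closed mesh, in model-units³.

    Raises
    ------
    MeshTopologyError
        If the mesh has boundary or non-manifold edges.
    """
    report = validate_mesh(mesh)
    if not report.closed:
        raise MeshTopologyError(
            f"mesh is not closed: {report.boundary_edge_count} boundary edge(s)"
        )
    if report.non_manifold_edge_count:
        raise MeshTopologyError(
            f"mesh has {report.non_manifold_edge_count} non-manifold edge(s)"
        )
    v = signed_volume(mesh)
    if v < 0:
        warnings.warn("mesh winding is inward (negative signed volume); using |V|", stacklevel=2)
    return abs(v)
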