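"""Meshes, surface elements and rigid-body poses.

A convex object's surface is discretized into oriented *surface elements*:
one per mesh triangle, carrying the triangle centroid, outward unit normal and
area.  Convexity guarantees that no element shadows another, so the radiation
field can later be evaluated independently (and vectorized) per element.

All lengths are meters; the base coordinate system is right-handed; a
:class:`Pose` maps local coordinates into the base frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh.exchange.stl

from .errors import EmptyMeshError, MeshFormatError, ValidationError

#: Facets with area below this (m^2) are flagged degenerate and skipped.
DEGENERATE_AREA = 1e-12

#: Default convexity tolerance (m): mesh discretization noise on cm-scale objects.
CONVEXITY_TOL = 1e-6

_ORTHO_TOL = 1e-10
_UNIT_TOL = 1e-9


# ---------------------------------------------------------------------------
# Pose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """A rigid transform stored as a 4x4 homogeneous matrix (local -> base)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"pose matrix must be 4x4, got {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValidationError("last row of a pose matrix must be [0, 0, 0, 1]")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL, rtol=0.0):
            raise ValidationError("pose rotation block is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > _ORTHO_TOL:
            raise ValidationError("pose rotation block must have determinant +1")
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "Pose":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def from_flat(cls, values) -> "Pose":
        """Build from 16 row-major numbers (the config representation)."""
        return cls(np.asarray(values, dtype=float).reshape(4, 4))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map points (N,3) or (3,) through the full homogeneous transform."""
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Map direction vectors through the rotation block only."""
        return np.asarray(vectors, float) @ self.rotation.T

    def compose(self, other: "Pose") -> "Pose":
        return Pose(self.matrix @ other.matrix)


def rotation_aligning_z(axis: np.ndarray) -> np.ndarray:
    """Smallest rotation taking the local +Z axis onto ``axis`` (unit)."""
    axis = unit(axis, "axis")
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about X
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def unit(vector, name: str = "vector") -> np.ndarray:
    """Return ``vector`` normalized, raising if it is (near) zero length."""
    v = np.asarray(vector, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise ValidationError(f"{name} has zero length")
    return v / n


def require_unit(vector, name: str = "normal") -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise ValidationError(f"{name} must be unit length, |{name}| = {np.linalg.norm(v):.6g}")
    return v


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """A triangulated surface: welded vertices, facets, outward unit normals.

    ``degenerate`` flags facets whose area is below :data:`DEGENERATE_AREA`;
    they are retained (ids stay aligned with the file) but excluded from
    element extraction and convexity checks.
    """

    vertices: np.ndarray            # (V, 3) m
    facets: np.ndarray              # (F, 3) int vertex indices
    facet_normals: np.ndarray       # (F, 3) unit, NaN rows for degenerate facets
    degenerate: np.ndarray = field(default=None)  # (F,) bool

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self.facets = np.asarray(self.facets, int).reshape(-1, 3)
        self.facet_normals = np.asarray(self.facet_normals, float).reshape(-1, 3)
        if self.facets.size and (self.facets.min() < 0 or self.facets.max() >= len(self.vertices)):
            raise ValidationError("facet references an out-of-range vertex index")
        if self.degenerate is None:
            self.degenerate = facet_areas(self.vertices, self.facets) < DEGENERATE_AREA
        self.degenerate = np.asarray(self.degenerate, bool)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    def facet_vertices(self) -> np.ndarray:
        """(F, 3, 3) array of per-facet vertex coordinates."""
        return self.vertices[self.facets]

    def surface_area(self) -> float:
        areas = facet_areas(self.vertices, self.facets)
        return float(np.sum(areas[~self.degenerate]))


def facet_areas(vertices: np.ndarray, facets: np.ndarray) -> np.ndarray:
    tri = vertices[facets]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def _winding_normals(vertices: np.ndarray, facets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed winding normals and areas; NaN normal where degenerate."""
    tri = vertices[facets]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norms
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / norms[:, None]
    normals[areas < DEGENERATE_AREA] = np.nan
    return normals, areas


def _precheck_binary_stl(path: str) -> None:
    """Report the byte offset at which a truncated binary STL ends."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(84)
    if len(head) < 84:
        raise MeshFormatError(
            f"{path}: binary STL truncated at byte {len(head)} (header needs 84 bytes)")
    n = int(np.frombuffer(head[80:84], dtype="<u4")[0])
    expected = 84 + 50 * n
    if size < expected:
        raise MeshFormatError(
            f"{path}: binary STL declares {n} facets ({expected} bytes) but ends at byte {size}")


def load_mesh(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    Vertices are welded on exact coordinate equality so binary and ASCII
    encodings of the same model yield identical facet/vertex sets.  File
    normals are trusted when they agree with the right-handed vertex winding
    (positive dot product) and recomputed from winding otherwise.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MeshFormatError(f"{path}: no such file")
    with open(path, "rb") as fh:
        start = fh.read(80)
    is_ascii = start.lstrip().lower().startswith(b"solid") and b"facet" in _head(path)
    if not is_ascii:
        _precheck_binary_stl(path)
    try:
        with open(path, "rb") as fh:
            raw = trimesh.exchange.stl.load_stl(fh)
    except Exception as exc:  # noqa: BLE001 - wrap into the documented error type
        raise MeshFormatError(f"{path}: unreadable STL ({exc})") from exc
    raw_vertices = np.asarray(raw["vertices"], float)
    raw_faces = np.asarray(raw["faces"], int)
    file_normals = np.asarray(raw.get("face_normals", np.zeros((len(raw_faces), 3))), float)
    if len(raw_faces) == 0:
        raise EmptyMeshError(f"{path}: STL contains no facets")

    # exact-coordinate vertex welding
    vertices, inverse = np.unique(raw_vertices, axis=0, return_inverse=True)
    facets = inverse.reshape(-1)[raw_faces]

    winding, areas = _winding_normals(vertices, facets)
    degenerate = areas < DEGENERATE_AREA
    agree = np.einsum("ij,ij->i", np.nan_to_num(winding), file_normals) > 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        file_unit = file_normals / np.linalg.norm(file_normals, axis=1)[:, None]
    normals = np.where((agree & np.isfinite(file_unit).all(axis=1))[:, None],
                       file_unit, winding)
    return TriangleMesh(vertices=vertices, facets=facets,
                        facet_normals=normals, degenerate=degenerate)


def _head(path: str, n: int = 4096) -> bytes:
    with open(path, "rb") as fh:
        return fh.read(n)


# ---------------------------------------------------------------------------
# Surface elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceElement:
    """An oriented point standing for a small surface patch."""

    id: int
    position: np.ndarray   # (3,) m
    normal: np.ndarray     # (3,) unit
    area: float            # m^2


class SurfaceElements:
    """Vectorized container of surface elements (ids, positions, normals, areas).

    Behaves as a sequence of :class:`SurfaceElement` while storing contiguous
    arrays for the field evaluation hot path.
    """

    def __init__(self, ids, positions, normals, areas):
        self.ids = np.asarray(ids, int).reshape(-1)
        self.positions = np.asarray(positions, float).reshape(-1, 3)
        self.normals = np.asarray(normals, float).reshape(-1, 3)
        self.areas = np.asarray(areas, float).reshape(-1)
        n = len(self.ids)
        if not (len(self.positions) == len(self.normals) == len(self.areas) == n):
            raise ValidationError("surface element arrays have mismatched lengths")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("surface element ids must be unique")
        lengths = np.linalg.norm(self.normals, axis=1)
        if n and np.max(np.abs(lengths - 1.0)) > _UNIT_TOL:
            raise ValidationError("surface element normals must be unit length")
        if n and np.min(self.areas) <= 0.0:
            raise ValidationError("surface element areas must be positive")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def __getitem__(self, i: int) -> SurfaceElement:
        return SurfaceElement(int(self.ids[i]), self.positions[i].copy(),
                              self.normals[i].copy(), float(self.areas[i]))

    @classmethod
    def from_sequence(cls, elements) -> "SurfaceElements":
        if isinstance(elements, cls):
            return elements
        elements = list(elements)
        return cls([e.id for e in elements],
                   [e.position for e in elements],
                   [e.normal for e in elements],
                   [e.area for e in elements])

    def total_area(self) -> float:
        return float(np.sum(self.areas))


def extract_surface_elements(mesh: TriangleMesh) -> SurfaceElements:
    """One element per non-degenerate facet: centroid, facet normal, area.

    Element ids are the facet indices in file order, so they stay stable
    across rigid transforms and across runs.
    """
    if mesh.n_facets == 0:
        raise EmptyMeshError("mesh has no facets")
    keep = ~mesh.degenerate
    if not keep.any():
        raise EmptyMeshError("all facets are degenerate; no surface elements")
    tri = mesh.facet_vertices()[keep]
    centroids = tri.mean(axis=1)
    areas = facet_areas(mesh.vertices, mesh.facets)[keep]
    normals = mesh.facet_normals[keep]
    ids = np.flatnonzero(keep)
    return SurfaceElements(ids, centroids, normals, areas)


def check_convexity(mesh: TriangleMesh, tol: float = CONVEXITY_TOL):
    """Is every vertex on or behind the supporting plane of every facet?

    Returns ``(is_convex, violating_facet_ids)``: a facet violates when some
    vertex lies more than ``tol`` in front of its plane along the outward
    normal.  Degenerate facets are skipped.
    """
    if tol < 0:
        raise ValidationError("convexity tolerance must be >= 0")
    keep = np.flatnonzero(~mesh.degenerate)
    if keep.size == 0:
        return True, []
    origins = mesh.vertices[mesh.facets[keep, 0]]          # (K, 3)
    normals = mesh.facet_normals[keep]                     # (K, 3)
    violating = []
    # blocked K x V signed-distance evaluation to bound memory
    block = max(1, int(4_000_000 // max(1, len(mesh.vertices))))
    for lo in range(0, keep.size, block):
        hi = min(lo + block, keep.size)
        signed = (mesh.vertices @ normals[lo:hi].T) - np.einsum(
            "ij,ij->i", origins[lo:hi], normals[lo:hi])
        bad = np.max(signed, axis=0) > tol
        violating.extend(int(keep[lo + i]) for i in np.flatnonzero(bad))
    return len(violating) == 0, violating


def transform_elements(elements, pose: Pose) -> SurfaceElements:
    """Rigidly transform elements: positions by the full transform, normals by
    the rotation block; ids and areas are untouched."""
    els = SurfaceElements.from_sequence(elements)
    return SurfaceElements(ids=els.ids.copy(),
                           positions=pose.apply_points(els.positions),
                           normals=pose.apply_vectors(els.normals),
                           areas=els.areas.copy())
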