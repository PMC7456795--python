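"""Exact 3D geometry primitives underlying every implantation-accuracy metric.

All coordinates are world millimetres.  Points and directions are plain
``numpy`` arrays of shape (3,); a trajectory is a :class:`Line3` (origin +
unit direction); head surfaces are triangle meshes (:class:`TriMesh`).

Every accuracy metric reduces to these primitives: lateral shift is
point-to-line distance, entry points come from line/mesh intersection,
implanted trajectories come from a total-least-squares line fit of contact
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "Line3",
    "TriMesh",
    "angle_between",
    "axial_coordinate",
    "euclidean_distance",
    "fit_line_tls",
    "lateral_shift",
    "line_mesh_intersections",
    "unit",
]

#: barycentric tolerance for ray-triangle tests
_BARY_EPS = 1e-9
#: duplicate intersection points closer than this (mm) are merged
_DEDUP_TOL = 1e-6


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident points, misses...)."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("non-finite coordinates")
    return a


def unit(v) -> np.ndarray:
    """Normalize ``v`` to unit length; error on (near-)zero vectors."""
    a = _as_point(v)
    n = float(np.linalg.norm(a))
    if n < 1e-12:
        raise GeometryError("cannot normalize a zero vector")
    return a / n


@dataclass(frozen=True)
class Line3:
    """An infinite oriented line: ``origin + t * direction``, t in mm.

    ``direction`` is normalized at construction; orientation is meaningful
    (trajectories are oriented proximal→distal, i.e. entry→target).
    """

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        object.__setattr__(self, "direction", unit(self.direction))

    @classmethod
    def through(cls, p, q) -> "Line3":
        """Line through two points, oriented p → q."""
        p, q = _as_point(p), _as_point(q)
        return cls(p, q - p)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + float(t) * self.direction


@dataclass
class TriMesh:
    """Triangle surface mesh in world millimetres.

    Faces are 0-based vertex index triples.  Degenerate (zero-area) faces
    are dropped at construction; out-of-range indices are an error.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError("vertices must have shape (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError("faces must have shape (m, 3)")
        if f.size == 0:
            raise GeometryError("mesh has no faces")
        if f.min() < 0 or f.max() >= len(v):
            raise GeometryError("face index out of range")
        # drop zero-area faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
        keep = area2 > 1e-12
        f = f[keep]
        if len(f) == 0:
            raise GeometryError("mesh has no non-degenerate faces")
        self.vertices = v
        self.faces = f

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def euclidean_distance(p, q) -> float:
    """Shortest distance between two points (mm)."""
    return float(np.linalg.norm(_as_point(p) - _as_point(q)))


def lateral_shift(p, line: Line3) -> float:
    """Shortest distance between a point and an infinite line (mm).

    This is the "lateral shift" deviation: the component of a point's
    displacement perpendicular to a planned trajectory.
    """
    d = _as_point(p) - line.origin
    return float(np.linalg.norm(d - np.dot(d, line.direction) * line.direction))


def axial_coordinate(p, line: Line3) -> float:
    """Signed scalar projection of ``p`` onto the line axis (mm).

    Positive in the direction of ``line.direction`` (distal, for a
    proximal→distal oriented trajectory); 0 at ``line.origin``.
    """
    return float(np.dot(_as_point(p) - line.origin, line.direction))


def angle_between(u, v) -> float:
    """Angle between two oriented directions, degrees in [0, 180].

    Directions are *not* folded to [0, 90]: trajectories are consistently
    oriented proximal→distal upstream, so planned-vs-implanted angles are
    small by construction and an obtuse angle signals an orientation bug.
    """
    un, vn = unit(u), unit(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(un, vn), -1.0, 1.0))))


def fit_line_tls(points, min_points: int = 2) -> Line3:
    """Total-least-squares line fit: minimizes squared *perpendicular* residuals.

    The line passes through the centroid with direction along the principal
    axis of the centered point cloud (leading right-singular vector).  The
    direction sign is chosen to point from the first listed point toward the
    last (nonnegative dot with ``last - first``); callers re-orient for the
    proximal→distal convention as needed.

    Raises
    ------
    GeometryError
        If fewer than ``min_points`` points are given, all points coincide
        ("degenerate fit"), or the two leading singular values are tied
        within 1e-9 relative ("ambiguous direction", isotropic cloud).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("points must have shape (n, 3)")
    if min_points < 2:
        raise GeometryError("min_points must be >= 2")
    if len(pts) < min_points:
        raise GeometryError(f"degenerate fit: need >= {min_points} points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered cloud: leading right-singular vector = TLS direction
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise GeometryError("degenerate fit: all points coincident")
    if len(s) > 1 and (s[0] - s[1]) / s[0] < 1e-9:
        raise GeometryError("ambiguous direction: tied principal axes")
    direction = vt[0]
    span = pts[-1] - pts[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    return Line3(centroid, direction)


def line_mesh_intersections(line: Line3, mesh: TriMesh):
    """All intersections of an infinite line with a triangle mesh.

    Vectorized Möller–Trumbore test against every face, with the line
    parameter unrestricted (both directions).  Returns a list of
    ``(point, t)`` tuples sorted by axial coordinate ``t`` ascending;
    hits closer than 1e-6 mm (shared edges/vertices) are deduplicated.
    An empty list means the line misses the mesh.
    """
    v, f = mesh.vertices, mesh.faces
    a = v[f[:, 0]]
    edge1 = v[f[:, 1]] - a
    edge2 = v[f[:, 2]] - a
    d = line.direction
    pvec = np.cross(d[None, :], edge2)
    det = np.einsum("ij,ij->i", edge1, pvec)
    ok = np.abs(det) > 1e-15
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    tvec = line.origin[None, :] - a
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, edge1)
    w = np.einsum("j,ij->i", d, qvec) * inv_det
    hit = (
        ok
        & (u >= -_BARY_EPS)
        & (w >= -_BARY_EPS)
        & (u + w <= 1.0 + _BARY_EPS)
    )
    if not np.any(hit):
        return []
    t = np.einsum("ij,ij->i", edge2, qvec)[hit] * inv_det[hit]
    order = np.argsort(t)
    t = t[order]
    out: list[tuple[np.ndarray, float]] = []
    for ti in t:
        if out and abs(ti - out[-1][1]) < _DEDUP_TOL:
            continue
        out.append((line.point_at(ti), float(ti)))
    return out
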