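"""Exact 3D distance primitives: point to segment, polyline and triangle mesh.

All coordinates are in millimetres. These primitives are the substrate for the
central measurement of the analysis — the shortest 3D distance between an
endocardial pace-mapping site and the phrenic-nerve course. Distances are
measured to the nerve *centerline* polyline, not to a rasterized tube surface;
the centerline convention is unambiguous and is used consistently throughout
(see docs/methods.md for the rationale and the switch points).

Points are plain ``(3,)`` float arrays; batches are ``(n, 3)``. ``Polyline3``
and ``TriangleMesh`` are thin validated containers around numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "Polyline3",
    "TriangleMesh",
    "point_to_segment_distance",
    "point_to_polyline_distance",
    "points_to_polyline_distances",
    "point_to_mesh_distance",
]


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("point has non-finite components")
    return p


@dataclass(frozen=True)
class Polyline3:
    """Ordered 3D polyline (mm) with per-vertex cumulative arc length.

    Invariants: at least two vertices, consecutive vertices distinct, hence
    strictly increasing arc length. A one-vertex *degenerate* polyline can only
    be built through :meth:`degenerate` and is flagged; it arises when a
    centerline is extracted from a single voxel.
    """

    vertices: np.ndarray
    is_degenerate: bool = field(default=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("polyline has non-finite vertices")
        if self.is_degenerate:
            if v.shape[0] != 1:
                raise ValueError("degenerate polyline must have exactly one vertex")
        else:
            if v.shape[0] < 2:
                raise ValueError("polyline needs at least 2 vertices")
            if np.any(np.linalg.norm(np.diff(v, axis=0), axis=1) == 0.0):
                raise ValueError("consecutive polyline vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def degenerate(cls, point) -> "Polyline3":
        return cls(np.asarray(point, dtype=float).reshape(1, 3), is_degenerate=True)

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length per vertex, mm; arc_length[0] == 0."""
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1]) if not self.is_degenerate else 0.0

    def sample(self, step_mm: float) -> np.ndarray:
        """Points at roughly ``step_mm`` arc-length spacing (vertices included)."""
        if self.is_degenerate:
            return self.vertices.copy()
        s = self.arc_length
        t = np.union1d(s, np.arange(0.0, s[-1], step_mm))
        out = np.empty((t.size, 3))
        for k in range(3):
            out[:, k] = np.interp(t, s, self.vertices[:, k])
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Polyline3":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return Polyline3(v, is_degenerate=self.is_degenerate)

    # CSV interchange: columns x_mm,y_mm,z_mm in path order
    def to_csv(self, path) -> None:
        np.savetxt(path, self.vertices, delimiter=",", header="x_mm,y_mm,z_mm", comments="")

    @classmethod
    def from_csv(cls, path) -> "Polyline3":
        v = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(v)


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh (mm). Zero-area faces are dropped on construction."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        # drop degenerate (zero-area) faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
        f = f[area2 > 0.0]
        if len(f) == 0:
            raise ValueError("mesh has no non-degenerate faces")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, m: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64))

    def save(self, path) -> None:
        """Write PLY or OBJ (by extension)."""
        self.as_trimesh().export(str(path))

    @classmethod
    def load(cls, path) -> "TriangleMesh":
        m = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(m)


def point_to_segment_distance(p, a, b):
    """Euclidean distance from ``p`` to the closed segment ``[a, b]``.

    Returns ``(distance_mm, closest_point)``. Rejects degenerate segments.
    """
    p, a, b = _as_point(p), _as_point(a), _as_point(b)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError("degenerate segment: a == b")
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    closest = a + t * ab
    return float(np.linalg.norm(p - closest)), closest


def _segments_closest_points(points: np.ndarray, va: np.ndarray, vb: np.ndarray):
    """Closest point on each segment (va[j], vb[j]) for each point.

    points: (n, 3); va, vb: (m, 3). Returns distances (n, m) and closest (n, m, 3).
    """
    ab = vb - va                              # (m, 3)
    denom = np.einsum("md,md->m", ab, ab)     # (m,)
    ap = points[:, None, :] - va[None, :, :]  # (n, m, 3)
    t = np.einsum("nmd,md->nm", ap, ab) / denom
    t = np.clip(t, 0.0, 1.0)
    closest = va[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d, closest


def point_to_polyline_distance(p, line: Polyline3):
    """Shortest distance from a point to a polyline.

    Returns ``(distance_mm, closest_point, segment_index)``; ties between
    segments are broken by the lowest segment index so the result is
    deterministic.
    """
    p = _as_point(p)
    if line.is_degenerate:
        q = line.vertices[0]
        return float(np.linalg.norm(p - q)), q.copy(), 0
    d, closest = _segments_closest_points(p[None, :], line.vertices[:-1], line.vertices[1:])
    j = int(np.argmin(d[0]))  # argmin returns the first minimum: lowest index
    return float(d[0, j]), closest[0, j], j


def points_to_polyline_distances(points, line: Polyline3) -> np.ndarray:
    """Vectorized shortest distances from many points to a polyline, mm."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if line.is_degenerate:
        return np.linalg.norm(points - line.vertices[0], axis=1)
    va, vb = line.vertices[:-1], line.vertices[1:]
    # chunk over points to bound the (n, m) intermediate
    out = np.empty(len(points))
    step = max(1, int(2e6 / max(len(va), 1)))
    for i in range(0, len(points), step):
        d, _ = _segments_closest_points(points[i : i + step], va, vb)
        out[i : i + step] = d.min(axis=1)
    return out


def _point_to_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Exact closest point on each triangle (a[j], b[j], c[j]) to point p.

    Vectorized barycentric-region classification (Ericson, Real-Time Collision
    Detection §5.1.5). Returns distances (m,) and closest points (m, 3).
    """
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("md,md->m", ab, ap)
    d2 = np.einsum("md,md->m", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("md,md->m", ab, bp)
    d4 = np.einsum("md,md->m", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("md,md->m", ab, cp)
    d6 = np.einsum("md,md->m", ac, cp)

    closest = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    reg = (d1 <= 0) & (d2 <= 0)                      # vertex a
    closest[reg] = a[reg]
    done |= reg

    reg = ~done & (d3 >= 0) & (d4 <= d3)             # vertex b
    closest[reg] = b[reg]
    done |= reg

    reg = ~done & (d6 >= 0) & (d5 <= d6)             # vertex c
    closest[reg] = c[reg]
    done |= reg

    vc = d1 * d4 - d3 * d2
    reg = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    closest[reg] = a[reg] + t[reg, None] * ab[reg]
    done |= reg

    vb_ = d5 * d2 - d1 * d6
    reg = ~done & (vb_ <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    closest[reg] = a[reg] + t[reg, None] * ac[reg]
    done |= reg

    va_ = d3 * d6 - d5 * d4
    reg = ~done & (va_ <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    closest[reg] = b[reg] + t[reg, None] * (c[reg] - b[reg])
    done |= reg

    reg = ~done                                       # interior
    denom = va_ + vb_ + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb_ / denom
        w = vc / denom
    closest[reg] = a[reg] + v[reg, None] * ab[reg] + w[reg, None] * ac[reg]

    d = np.linalg.norm(p[None, :] - closest, axis=1)
    return d, closest


def point_to_mesh_distance(p, mesh: TriangleMesh):
    """Exact shortest distance from a point to a triangle mesh surface.

    Minimum over all faces of the exact point-to-triangle distance; ties go to
    the lowest face index. Returns ``(distance_mm, closest_point)``.
    """
    p = _as_point(p)
    f = mesh.faces
    a, b, c = mesh.vertices[f[:, 0]], mesh.vertices[f[:, 1]], mesh.vertices[f[:, 2]]
    d, closest = _point_to_triangles(p, a, b, c)
    j = int(np.argmin(d))
    return float(d[j]), closest[j]
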