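"""Dimension-exact 3D primitives and geometric kernels.

Everything downstream — axis extraction, angle measurement, the synthetic
generator — is built on the handful of operations here: algebraic sphere
fitting, plane/mesh cross-sectioning with closed-contour assembly, planar
polygon centroid/area, and direction projections/angles.

Conventions: lengths in mm, angles in degrees at the API surface (radians
internally), directions are unit vectors (float64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import Polygon

__all__ = [
    "GeometryError",
    "DegenerateInputError",
    "Line3",
    "Plane",
    "PlanarContour",
    "unit",
    "plane_basis",
    "fit_sphere",
    "section_mesh",
    "contour_centroid_area",
    "project_direction_onto_plane",
    "angle_deg",
    "signed_angle_in_plane",
]

_UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """A geometric operation failed (degenerate or inconsistent input)."""


class DegenerateInputError(GeometryError):
    """Input configuration admits no unique answer (coplanar points, etc.)."""


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalized to Euclidean length 1."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _UNIT_TOL:
        raise DegenerateInputError("cannot normalize a zero-length vector")
    return v / n


@dataclass(frozen=True)
class Line3:
    """A 3D line: point plus unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction))

    def closest_point(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        t = np.dot(p - self.origin, self.direction)
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Plane:
    """A 3D plane: point plus unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return (p - self.point) @ self.normal


@dataclass
class PlanarContour:
    """An ordered loop of 3D points lying in a common plane.

    ``vertices`` has shape (n, 3); when ``closed`` the last vertex connects
    back to the first (the first vertex is not repeated).
    """

    plane: Plane
    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.closed and len(self.vertices) < 3:
            raise GeometryError("a closed contour needs at least 3 vertices")

    def __len__(self) -> int:
        return len(self.vertices)


def plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (u, v) with u × v = normal."""
    n = plane.normal
    # pick the world axis least aligned with the normal as seed
    seed = np.eye(3)[np.argmin(np.abs(n))]
    u = unit(np.cross(n, seed))
    v = np.cross(n, u)
    return u, v


def to_plane_coords(points: np.ndarray, plane: Plane) -> np.ndarray:
    """Map 3D points into the plane's 2D chart."""
    u, v = plane_basis(plane)
    d = np.asarray(points, dtype=float) - plane.point
    return np.column_stack([d @ u, d @ v])


def from_plane_coords(xy: np.ndarray, plane: Plane) -> np.ndarray:
    """Inverse of :func:`to_plane_coords`."""
    u, v = plane_basis(plane)
    xy = np.asarray(xy, dtype=float)
    return plane.point + np.outer(xy[..., 0], u) + np.outer(xy[..., 1], v)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Solves the linear system obtained from expanding
    ``|p - c|^2 = r^2``  ⇒  ``2 p·c + (r^2 - |c|^2) = |p|^2``,
    which is exact on noiseless sphere samples and needs no initialization.

    Parameters
    ----------
    points : (n, 3) array, n >= 4, not all coplanar.

    Returns
    -------
    center : (3,) array
    radius : float
    rms : float
        Root-mean-square of the geometric residuals ``|p - c| - r``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateInputError("sphere fit needs >= 4 points of shape (n, 3)")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    # coplanar point sets make A rank-deficient (the normal direction is free)
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-9 * max(1.0, np.abs(pts).max())) < 4:
        # rank of centered [2p | 1] is 1 + rank of centered points
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-7 * max(1.0, np.abs(pts).max())) < 3:
            raise DegenerateInputError("sphere fit is degenerate: points are coplanar")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateInputError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


# ---------------------------------------------------------------------------
# plane/mesh sectioning
# ---------------------------------------------------------------------------

def _assemble_loops(segments: np.ndarray, tol: float) -> list[np.ndarray]:
    """Chain unordered intersection segments into closed vertex loops.

    Endpoints are welded by rounding to ``tol``; open chains (from numerically
    grazing intersections) are dropped — only closed loops are returned.
    """
    if len(segments) == 0:
        return []
    keys = np.round(segments / tol).astype(np.int64)  # (n, 2, 3)
    index: dict[tuple, int] = {}
    coords: list[np.ndarray] = []

    def vid(k, p) -> int:
        t = tuple(k)
        if t not in index:
            index[t] = len(coords)
            coords.append(p)
        return index[t]

    adj: dict[int, set[int]] = {}
    for (ka, kb), (pa, pb) in zip(keys, segments):
        a, b = vid(ka, pa), vid(kb, pb)
        if a == b:  # zero-length sliver
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    loops: list[np.ndarray] = []
    visited: set[int] = set()
    for start in list(adj):
        if start in visited or len(adj.get(start, ())) != 2:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        closed = False
        while True:
            nxt = [n for n in adj[cur] if n != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                closed = True
                break
            if cur in visited or len(adj.get(cur, ())) != 2:
                break
            visited.add(cur)
            loop.append(cur)
        if closed and len(loop) >= 3:
            loops.append(np.array([coords[i] for i in loop]))
    return loops


def section_mesh(mesh: trimesh.Trimesh, plane: Plane) -> list[PlanarContour]:
    """Intersect a triangle mesh with a plane.

    Returns every closed intersection loop as an ordered :class:`PlanarContour`
    (an empty list when the plane misses the mesh). If the plane coincides
    with mesh vertices/faces closely enough that loop assembly fails, the
    plane is nudged by 1e-7 of the mesh scale along its normal and the
    section is retried.
    """
    scale = float(mesh.scale) if mesh.scale > 0 else 1.0
    weld = 1e-9 * scale

    def attempt(pl: Plane) -> list[np.ndarray]:
        segs = trimesh.intersections.mesh_plane(
            mesh, plane_normal=pl.normal, plane_origin=pl.point
        )
        return _assemble_loops(np.asarray(segs, dtype=float), weld)

    loops = attempt(plane)
    if not loops:
        # distinguish "no intersection" from "degenerate coincidence"
        d = plane.signed_distance(mesh.vertices)
        if d.min() > 0 or d.max() < 0:
            return []
        nudged = Plane(plane.point + 1e-7 * scale * plane.normal, plane.normal)
        loops = attempt(nudged)
    return [PlanarContour(plane, lp, closed=True) for lp in loops]


def contour_centroid_area(contour: PlanarContour) -> tuple[np.ndarray, float]:
    """Area and area-weighted centroid of a closed planar contour.

    The contour is mapped into the plane's 2D chart; the shoelace formula
    gives the signed area and first moments, and the centroid is mapped back
    to 3D. Self-intersecting contours are rejected.
    """
    if not contour.closed:
        raise GeometryError("centroid/area require a closed contour")
    xy = to_plane_coords(contour.vertices, contour.plane)
    if not Polygon(xy).is_simple:
        raise GeometryError("contour is self-intersecting")
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a2 = cross.sum()  # twice the signed area
    if abs(a2) < 1e-14:
        raise DegenerateInputError("contour has zero area")
    cx = ((x + xn) * cross).sum() / (3.0 * a2)
    cy = ((y + yn) * cross).sum() / (3.0 * a2)
    centroid = from_plane_coords(np.array([[cx, cy]]), contour.plane)[0]
    return centroid, float(abs(a2) / 2.0)


def points_inside_mesh(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity containment test for a watertight mesh.

    Casts one ray per query point along a fixed irrational direction and
    counts triangle crossings (vectorized Möller–Trumbore); an odd count
    means inside. Self-contained so no spatial-index backend is required.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    direction = unit(np.array([0.2886751, 0.5773503, 0.7637626]))
    tri = mesh.triangles  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    valid_tri = np.abs(a) > 1e-12
    inv_a = np.where(valid_tri, 1.0 / np.where(valid_tri, a, 1.0), 0.0)
    inside = np.zeros(len(points), dtype=bool)
    chunk = max(1, int(2e6 // max(len(tri), 1)))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]  # (k, 3)
        s = p[:, None, :] - v0[None, :, :]  # (k, m, 3)
        u = np.einsum("kmj,mj->km", s, h) * inv_a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("kmj,j->km", q, direction) * inv_a
        t = np.einsum("kmj,mj->km", q, e2) * inv_a
        hit = (
            valid_tri[None, :]
            & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 1e-9)
        )
        inside[start : start + chunk] = hit.sum(axis=1) % 2 == 1
    return inside


# ---------------------------------------------------------------------------
# projections and angles
# ---------------------------------------------------------------------------

def project_direction_onto_plane(d: np.ndarray, plane: Plane) -> np.ndarray:
    """Unit component of direction ``d`` orthogonal to the plane normal."""
    d = unit(d)
    proj = d - (d @ plane.normal) * plane.normal
    n = np.linalg.norm(proj)
    if n < 1e-9:
        raise DegenerateInputError(
            "direction is parallel to the plane normal; projection undefined"
        )
    return proj / n


def angle_deg(u: np.ndarray, v: np.ndarray, acute: bool = False) -> float:
    """Angle between two directions in degrees.

    ``acute=False`` gives the full angle in [0, 180]; ``acute=True`` folds it
    into [0, 90] using ``|u·v|``.
    """
    c = float(np.clip(unit(u) @ unit(v), -1.0, 1.0))
    if acute:
        c = abs(c)
    return float(np.degrees(np.arccos(c)))


def signed_angle_in_plane(
    u: np.ndarray, v: np.ndarray, normal: np.ndarray, tol_deg: float = 1.0
) -> float:
    """Right-handed signed angle from ``u`` to ``v`` about ``normal``, (-180, 180].

    Both directions must lie in the plane (within ``tol_deg`` of orthogonal to
    the normal).
    """
    u, v, n = unit(u), unit(v), unit(normal)
    lim = np.sin(np.radians(tol_deg))
    if abs(u @ n) > lim or abs(v @ n) > lim:
        raise GeometryError("inputs are not in the plane of the given normal")
    ang = np.degrees(np.arctan2(np.cross(u, v) @ n, u @ v))
    return float(ang if ang > -180.0 else 180.0)
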