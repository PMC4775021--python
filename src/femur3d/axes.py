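"""Anatomical axes and landmarks of a femur surface model.

The measurement chain implemented here follows the classical 3D definition
of proximal femoral geometry:

* the **proximal shaft axis** connects the centroids of the medullary-canal
  (inner cortical) cross sections at 25 % and 35 % of bone length, measured
  from the tip of the greater trochanter toward the facies patellaris saddle
  point — deliberately below the lesser trochanter and above the bowed
  middle third;
* the **femoral head center** is the center of a least-squares sphere fitted
  to the articular head surface;
* the **neck isthmus** is the narrowest cross section of the neck, located
  by an iterative minimal-area sweep;
* head center and isthmus centroid connect to give the **true femoral neck
  axis**;
* the **posterior condylar tangent** ("table-top" line) touches the
  posterior peaks of both condyles and, together with the shaft axis,
  defines the frontal and transversal reference planes.

All positions are in mm in the mesh's own frame; every output is equivariant
under rigid motions of the input bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

from .geometry import (
    DegenerateInputError,
    GeometryError,
    Line3,
    Plane,
    contour_centroid_area,
    fit_sphere,
    plane_basis,
    project_direction_onto_plane,
    section_mesh,
    unit,
)

log = logging.getLogger(__name__)

TROCHANTER_TIP = "trochanter_tip"
PATELLAR_SADDLE = "facies_patellaris_saddle"


class MeasurementError(GeometryError):
    """A stage of the measurement chain failed; the message names the stage."""


@dataclass
class BoneModel:
    """A segmented femur: outer cortical surface plus medullary-canal surface.

    Landmarks (mm, same frame as the meshes) may carry ``trochanter_tip`` and
    ``facies_patellaris_saddle``; synthetic bones always do, real bones may
    rely on the heuristic detectors below.
    """

    outer: trimesh.Trimesh
    inner: trimesh.Trimesh | None = None
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    side: str = "left"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    def inner_containment_fraction(self, n_sample: int = 300, seed: int = 0) -> float:
        """Fraction of sampled inner-surface vertices inside the outer surface."""
        if self.inner is None:
            raise MeasurementError("bone has no inner (medullary canal) mesh")
        from .geometry import points_inside_mesh

        rng = np.random.default_rng(seed)
        verts = self.inner.vertices
        idx = rng.choice(len(verts), size=min(n_sample, len(verts)), replace=False)
        return float(np.mean(points_inside_mesh(self.outer, verts[idx])))

    def mirrored(self) -> "BoneModel":
        """Reflect across a sagittal-type plane, flipping the recorded side.

        Measurements are rigid-motion invariant, so the mirror plane can be
        any fixed plane; x = centroid_x is used.
        """
        cx = float(self.outer.vertices[:, 0].mean())

        def refl_mesh(m: trimesh.Trimesh) -> trimesh.Trimesh:
            v = m.vertices.copy()
            v[:, 0] = 2.0 * cx - v[:, 0]
            return trimesh.Trimesh(vertices=v, faces=m.faces[:, ::-1], process=False)

        lm = {}
        for k, p in self.landmarks.items():
            q = p.copy()
            q[0] = 2.0 * cx - q[0]
            lm[k] = q
        return BoneModel(
            outer=refl_mesh(self.outer),
            inner=None if self.inner is None else refl_mesh(self.inner),
            landmarks=lm,
            side="right" if self.side == "left" else "left",
        )


@dataclass
class FemoralAxes:
    """The derived geometric frame of one femur."""

    shaft_axis: Line3
    neck_axis: Line3
    head_center: np.ndarray
    head_radius: float
    isthmus_centroid: np.ndarray
    isthmus_area: float
    condylar_line: Line3
    frontal: Plane
    transversal: Plane
    bone_length: float


class IsthmusResult(NamedTuple):
    centroid: np.ndarray
    area: float
    direction: np.ndarray
    n_iterations: int
    flags: tuple[str, ...]


class CondylarResult(NamedTuple):
    line: Line3
    posterior: np.ndarray  # unit vector, points posteriorly in the transversal plane


# ---------------------------------------------------------------------------
# orientation and length
# ---------------------------------------------------------------------------

def longitudinal_direction(bone: BoneModel) -> np.ndarray:
    """First principal axis of the outer surface, oriented proximal→distal.

    A second PCA pass restricted to the mid-shaft band (30–80 % along the
    first-pass axis) removes the tilt that the asymmetric epiphyses (head,
    condyles) induce in a whole-surface principal axis.
    """
    verts = bone.outer.vertices
    centered = verts - verts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    tip = bone.landmarks.get(TROCHANTER_TIP)
    if tip is None:
        tip = detect_trochanter_tip(bone, d)
    # proximal→distal points away from the trochanter tip; orient before the
    # band refinement so the (asymmetric) band is frame-independent
    if (tip - verts.mean(axis=0)) @ d > 0:
        d = -d
    if s[1] > 0 and s[0] / s[1] < 2.0:
        log.warning("longitudinal_direction: degenerate aspect ratio %.2f (< 2)", s[0] / s[1])
    else:
        t = centered @ d
        lo, hi = np.quantile(t, [0.30, 0.80])
        band = centered[(t > lo) & (t < hi)]
        if len(band) > 100:
            d_ref = np.linalg.svd(band - band.mean(axis=0), full_matrices=False)[2][0]
            d = d_ref if d_ref @ d > 0 else -d_ref
    return unit(d)


def detect_trochanter_tip(bone: BoneModel, long_dir: np.ndarray | None = None) -> np.ndarray:
    """Heuristic trochanter tip: extreme outer vertex along the proximal
    direction within the lateral half of the proximal end.

    Used only when the landmark is absent; not claimed anatomically validated.
    """
    verts = bone.outer.vertices
    if long_dir is None:
        centered = verts - verts.mean(axis=0)
        long_dir = np.linalg.svd(centered, full_matrices=False)[2][0]
    t = verts @ long_dir
    # the proximal end is the one with the larger off-axis spread (head + trochanter)
    lo_mask = t < np.quantile(t, 0.25)
    hi_mask = t > np.quantile(t, 0.75)
    axis_pt = verts.mean(axis=0)

    def spread(mask):
        d = verts[mask] - axis_pt
        d -= np.outer(d @ long_dir, long_dir)
        return np.linalg.norm(d, axis=1).max()

    proximal_sign = 1.0 if spread(hi_mask) >= spread(lo_mask) else -1.0
    proximal = proximal_sign * np.asarray(long_dir)
    # lateral half: opposite the head; the head is the farthest off-axis point
    tp = verts @ proximal
    top = verts[tp > np.quantile(tp, 0.70)]
    off = top - axis_pt
    off -= np.outer(off @ proximal, proximal)
    head_side = unit(off[np.argmax(np.linalg.norm(off, axis=1))])
    lateral = top[(top - axis_pt) @ head_side < 0]
    if len(lateral) == 0:
        lateral = top
    return lateral[np.argmax(lateral @ proximal)].copy()


def detect_patellar_saddle(bone: BoneModel, long_dir: np.ndarray | None = None) -> np.ndarray:
    """Heuristic facies-patellaris saddle: midpoint of the distal anterior
    groove, approximated by the distal-end vertex closest to the long axis
    among anterior vertices. Used only when the landmark is absent."""
    verts = bone.outer.vertices
    if long_dir is None:
        long_dir = longitudinal_direction(bone)
    t = verts @ long_dir
    distal = verts[t > np.quantile(t, 0.92)]
    center = distal.mean(axis=0)
    off = distal - center
    off -= np.outer(off @ long_dir, long_dir)
    r = np.linalg.norm(off, axis=1)
    # anterior ≈ opposite the condylar mass
    posterior = unit((distal.mean(axis=0) - verts.mean(axis=0))
                     - ((distal.mean(axis=0) - verts.mean(axis=0)) @ long_dir) * long_dir) \
        if np.linalg.norm(off) > 0 else None
    anterior_score = -(off @ posterior) if posterior is not None else np.zeros(len(distal))
    cand = distal[(anterior_score > 0) & (r < np.quantile(r, 0.5))]
    if len(cand) == 0:
        cand = distal
    return cand[np.argmax(cand @ long_dir)].copy()


def _landmark(bone: BoneModel, name: str, allow_heuristics: bool) -> np.ndarray:
    if name in bone.landmarks:
        return bone.landmarks[name]
    if not allow_heuristics:
        raise MeasurementError(f"bone_length: landmark {name!r} missing and heuristics disabled")
    if name == TROCHANTER_TIP:
        return detect_trochanter_tip(bone)
    if name == PATELLAR_SADDLE:
        return detect_patellar_saddle(bone)
    raise MeasurementError(f"unknown landmark {name!r}")


def bone_length(bone: BoneModel, allow_heuristics: bool = False) -> float:
    """Tip of the greater trochanter to the facies patellaris saddle point, mm."""
    tip = _landmark(bone, TROCHANTER_TIP, allow_heuristics)
    saddle = _landmark(bone, PATELLAR_SADDLE, allow_heuristics)
    return float(np.linalg.norm(tip - saddle))


def level_plane(bone: BoneModel, fraction: float, allow_heuristics: bool = False) -> Plane:
    """Cross-section plane at ``fraction`` of bone length distal of the
    trochanter tip, perpendicular to the longitudinal direction."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    d = longitudinal_direction(bone)
    tip = _landmark(bone, TROCHANTER_TIP, allow_heuristics)
    length = bone_length(bone, allow_heuristics)
    return Plane(tip + fraction * length * d, d)


# ---------------------------------------------------------------------------
# shaft axis
# ---------------------------------------------------------------------------

def inner_cortical_midpoint(
    bone: BoneModel, fraction: float, allow_heuristics: bool = False
) -> np.ndarray:
    """Centroid of the largest inner-cortical cross section at the given level."""
    if bone.inner is None:
        raise MeasurementError("proximal_shaft_axis: bone has no inner (medullary canal) mesh")
    plane = level_plane(bone, fraction, allow_heuristics)
    contours = section_mesh(bone.inner, plane)
    if not contours:
        raise MeasurementError(
            f"proximal_shaft_axis: inner surface has no cross section at {fraction:.0%} of bone length"
        )
    # cortical shells can split into several loops; the canal is the largest
    best = max(contours, key=lambda c: contour_centroid_area(c)[1])
    centroid, _ = contour_centroid_area(best)
    return centroid


def proximal_shaft_axis(bone: BoneModel, allow_heuristics: bool = False) -> Line3:
    """Line through the inner cortical midpoints at 25 % and 35 % of bone
    length, oriented proximal→distal."""
    p25 = inner_cortical_midpoint(bone, 0.25, allow_heuristics)
    p35 = inner_cortical_midpoint(bone, 0.35, allow_heuristics)
    if np.linalg.norm(p35 - p25) < 1e-6:
        raise MeasurementError("proximal_shaft_axis: 25% and 35% midpoints coincide")
    d = unit(p35 - p25)
    if d @ longitudinal_direction(bone) < 0:
        d = -d
    return Line3(p25, d)


# ---------------------------------------------------------------------------
# femoral head
# ---------------------------------------------------------------------------

def femoral_head_center(
    bone: BoneModel,
    hint: np.ndarray | None = None,
    shaft_axis: Line3 | None = None,
    rms_gate: float = 1.0,
    radius_range: tuple[float, float] = (10.0, 40.0),
) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere fit to the articular head surface.

    Head vertices are selected around a seed point: the ``hint`` if given,
    else the farthest off-axis vertex of the proximal, medial half of the
    bone (medial = opposite the greater trochanter). The fit is then
    iterated with trimming of residuals beyond 2× RMS so neck vertices
    contaminating the cap are discarded.

    ``shaft_axis``, when available, is the off-axis reference; otherwise the
    principal axis is used (slightly biased toward the head mass).

    Returns ``(center, radius, rms)``; refuses when the final RMS residual
    exceeds ``rms_gate`` (mm).
    """
    verts = bone.outer.vertices
    long_dir = longitudinal_direction(bone)

    if hint is not None:
        hint = np.asarray(hint, dtype=float)
        sel = verts[np.linalg.norm(verts - hint, axis=1) < 35.0]
        if len(sel) < 10:
            raise MeasurementError("femoral_head_center: no surface near the given hint")
        seed_pt = sel[np.argmin(np.linalg.norm(sel - hint, axis=1))]
    else:
        t = verts @ long_dir
        prox = verts[t < np.quantile(t, 0.22)]  # proximal ~fifth of the bone
        tip = bone.landmarks.get(TROCHANTER_TIP)
        if tip is None:
            tip = detect_trochanter_tip(bone, long_dir)
        prox = prox[np.linalg.norm(prox - tip, axis=1) > 25.0]
        if len(prox) < 10:
            raise MeasurementError("femoral_head_center: proximal selection empty")
        if shaft_axis is not None:
            axis_pt, axis_dir = shaft_axis.origin, shaft_axis.direction
        else:
            axis_pt, axis_dir = verts.mean(axis=0), long_dir
        off = prox - axis_pt
        off -= np.outer(off @ axis_dir, axis_dir)
        tip_off = tip - axis_pt
        tip_off = tip_off - (tip_off @ axis_dir) * axis_dir
        medial = off @ tip_off < 0  # head lies opposite the trochanter
        cand, cand_off = (prox[medial], off[medial]) if medial.sum() >= 10 else (prox, off)
        seed_pt = cand[np.argmax(np.linalg.norm(cand_off, axis=1))]

    cap = verts[np.linalg.norm(verts - seed_pt, axis=1) < 18.0]
    if len(cap) < 10:
        raise MeasurementError("femoral_head_center: head cap selection empty")
    center, radius, rms = fit_sphere(cap)
    radius = float(np.clip(radius, 8.0, 50.0))

    for _ in range(4):
        sel = verts[np.linalg.norm(verts - center, axis=1) < 1.15 * radius]
        if len(sel) < 10:
            break
        center, radius, rms = fit_sphere(sel)
        resid = np.abs(np.linalg.norm(sel - center, axis=1) - radius)
        keep = sel[resid < max(2.0 * rms, 1e-6)]
        if len(keep) >= 10 and len(keep) < len(sel):
            center, radius, rms = fit_sphere(keep)

    if rms > rms_gate:
        raise MeasurementError(
            f"femoral_head_center: low sphericity (RMS {rms:.2f} mm > gate {rms_gate} mm)"
        )
    if not radius_range[0] < radius < radius_range[1]:
        log.warning("femoral_head_center: radius %.1f mm outside %s", radius, radius_range)
    return center, float(radius), float(rms)


# ---------------------------------------------------------------------------
# neck isthmus and neck axis
# ---------------------------------------------------------------------------

def _contour_near_axis(contours, origin, direction, max_offaxis=20.0):
    """Pick the section contour whose centroid is nearest the candidate neck
    axis (largest-area selection would grab the head or shaft here)."""
    best, best_d, best_area = None, np.inf, np.nan
    for c in contours:
        try:
            centroid, area = contour_centroid_area(c)
        except GeometryError:
            continue
        d = np.linalg.norm(np.cross(centroid - origin, direction))
        if d < best_d:
            best, best_d, best_area = centroid, d, area
    if best is None or best_d > max_offaxis:
        return None
    return best, best_area


def neck_isthmus(
    bone: BoneModel,
    head_center: np.ndarray,
    shaft_axis: Line3,
    head_radius: float | None = None,
    station_step: float = 1.0,
    tol: float = 0.1,
    max_iter: int = 20,
) -> IsthmusResult:
    """Iterative minimal-cross-section search for the neck isthmus.

    The candidate neck direction starts as head-center → closest point on the
    shaft axis. Section planes perpendicular to the candidate direction are
    swept over stations between 0.25× and 0.9× of the head-to-shaft distance
    (1 mm apart); the station of minimal outer-contour area defines the new
    isthmus centroid, the direction is updated to head-center → centroid, and
    the sweep repeats until the centroid moves < ``tol`` mm (max 20 rounds).

    When ``head_radius`` is given, stations inside the head sphere are
    excluded: for a steep (valga) neck the 0.25× station can fall inside the
    head, where a grazing cross section of the sphere has near-zero area and
    would hijack the minimum.
    """
    head_center = np.asarray(head_center, dtype=float)
    foot = shaft_axis.closest_point(head_center)
    dist = float(np.linalg.norm(foot - head_center))
    if dist < 1e-6:
        raise MeasurementError("neck_isthmus: head center lies on the shaft axis")
    direction = unit(foot - head_center)
    flags: list[str] = []
    centroid_prev: np.ndarray | None = None

    s_min = 0.25 * dist
    if head_radius is not None:
        s_min = max(s_min, head_radius + max(1.0, station_step))
    s_max = max(0.9 * dist, s_min + 12.0)

    # restrict sectioning to faces near the head→shaft segment: sweeping the
    # full cortical surface dozens of times would dominate the runtime
    tri_centers = bone.outer.triangles_center
    seg = foot - head_center
    t_par = np.clip((tri_centers - head_center) @ seg / (seg @ seg), -0.3, 1.3)
    d_seg = np.linalg.norm(tri_centers - (head_center + t_par[:, None] * seg), axis=1)
    sub_faces = bone.outer.faces[d_seg < 1.75 * max(40.0, dist * 0.5)]
    neck_region = trimesh.Trimesh(
        vertices=bone.outer.vertices, faces=sub_faces, process=False
    )

    for it in range(1, max_iter + 1):
        stations = np.arange(s_min, s_max + 1e-9, station_step)
        areas, centroids = [], []
        for s in stations:
            plane = Plane(head_center + s * direction, direction)
            contours = section_mesh(neck_region, plane)
            if not contours:
                continue
            pick = _contour_near_axis(
                contours, head_center, direction, max_offaxis=max(25.0, dist)
            )
            if pick is None:
                continue
            centroids.append(pick[0])
            areas.append(pick[1])
        if not areas:
            raise MeasurementError("neck_isthmus: no cross sections found along the neck")
        areas = np.asarray(areas)
        k = int(np.argmin(areas))
        if areas.max() - areas.min() < 0.01 * areas.min():
            # cylindrical neck: no waist — take the middle station, flag it
            k = len(areas) // 2
            flags.append("flat_minimum")
        centroid, area = centroids[k], float(areas[k])
        if centroid_prev is not None and np.linalg.norm(centroid - centroid_prev) < tol:
            return IsthmusResult(centroid, area, unit(head_center - centroid), it, tuple(flags))
        centroid_prev = centroid
        direction = unit(centroid - head_center)
    raise MeasurementError(
        f"neck_isthmus: no convergence after {max_iter} iterations "
        f"(last centroid {np.round(centroid_prev, 2).tolist()})"
    )


def neck_axis(head_center: np.ndarray, isthmus_centroid: np.ndarray) -> Line3:
    """True femoral neck axis: the line connecting isthmus centroid and head
    center, oriented isthmus → head (medially)."""
    head_center = np.asarray(head_center, dtype=float)
    isthmus_centroid = np.asarray(isthmus_centroid, dtype=float)
    if np.linalg.norm(head_center - isthmus_centroid) < 1e-6:
        raise MeasurementError("neck_axis: head center and isthmus centroid coincide")
    return Line3(isthmus_centroid, head_center - isthmus_centroid)


# ---------------------------------------------------------------------------
# condylar tangent and reference planes
# ---------------------------------------------------------------------------

def condylar_tangent_line(
    bone: BoneModel,
    transversal_normal: np.ndarray,
    min_support: float = 15.0,
    allow_heuristics: bool = False,
) -> CondylarResult:
    """Posterior intercondylar tangent by the table-top method.

    Vertices of the distal 25 % of the bone are projected into the plane
    perpendicular to ``transversal_normal``; the tangent is the 2D convex-hull
    edge whose outward normal points posterior and whose two support vertices
    are at least ``min_support`` mm apart (one per condyle).
    """
    n = unit(transversal_normal)
    verts = bone.outer.vertices
    tip = _landmark(bone, TROCHANTER_TIP, allow_heuristics)
    length = bone_length(bone, allow_heuristics)
    t = (verts - tip) @ n
    distal = verts[t > 0.75 * length]
    if len(distal) < 10:
        raise MeasurementError("condylar_tangent_line: distal 25% selection empty")

    plane = Plane(tip, n)
    u, v = plane_basis(plane)
    xy = np.column_stack([(distal - tip) @ u, (distal - tip) @ v])

    # posterior hint: the condylar mass sits behind the shaft axis
    deep = verts[t > 0.90 * length]
    shaft_pt = verts[(t > 0.55 * length) & (t < 0.75 * length)].mean(axis=0)
    post3 = deep.mean(axis=0) - shaft_pt
    post3 -= (post3 @ n) * n
    if np.linalg.norm(post3) < 1e-9:
        raise MeasurementError("condylar_tangent_line: cannot orient posterior direction")
    post2 = unit(np.array([post3 @ u, post3 @ v]))

    hull = ConvexHull(xy)
    best_len, best_pair = 0.0, None
    for i, j in hull.simplices:
        e = xy[j] - xy[i]
        elen = np.linalg.norm(e)
        if elen < 1e-9:
            continue
        out = np.array([e[1], -e[0]]) / elen
        centroid2 = xy[hull.vertices].mean(axis=0)
        if out @ (xy[i] - centroid2) < 0:
            out = -out
        if out @ post2 > np.cos(np.radians(40.0)) and elen >= min_support and elen > best_len:
            best_len, best_pair = elen, (i, j)
    if best_pair is None:
        raise MeasurementError(
            "condylar_tangent_line: no posterior hull edge with support "
            f">= {min_support} mm (single condyle?)"
        )
    p, q = distal[best_pair[0]], distal[best_pair[1]]
    return CondylarResult(Line3(p, q - p), unit(post3))


def reference_planes(
    shaft_axis: Line3, condylar_line: Line3, anterior_hint: np.ndarray
) -> tuple[Plane, Plane]:
    """Frontal and transversal reference planes.

    The transversal plane is perpendicular to the shaft axis. The frontal
    plane contains the shaft axis and the condylar direction projected onto
    the transversal plane; its normal is oriented anterior (``anterior_hint``
    fixes the sign).
    """
    transversal = Plane(shaft_axis.origin, shaft_axis.direction)
    proj_cond = project_direction_onto_plane(condylar_line.direction, transversal)
    n = np.cross(shaft_axis.direction, proj_cond)
    if np.linalg.norm(n) < 1e-9:
        raise MeasurementError("reference_planes: shaft axis parallel to condylar line")
    n = unit(n)
    if n @ np.asarray(anterior_hint, dtype=float) < 0:
        n = -n
    return Plane(shaft_axis.origin, n), transversal
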