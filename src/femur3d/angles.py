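"""Neck-shaft (CCD) angle, femoral torsion, and the full measurement chain.

The CCD angle is the full 3D angle between the neck axis (isthmus → head)
and the proximal shaft axis (proximal → distal) — no projection, since both
axes are true 3D lines. Femoral torsion is measured by the table-top
convention: the neck axis is projected onto the transversal plane and the
acute angle to the posterior intercondylar tangent is taken, signed positive
when the head end of the projection points anterior (anteversion) and
negative when posterior (retroversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from . import axes as ax
from .axes import BoneModel, FemoralAxes, MeasurementError
from .geometry import angle_deg, project_direction_onto_plane


@dataclass
class MeasureConfig:
    """Tunable gates of the measurement chain (mm / degrees)."""

    head_rms_gate: float = 1.0
    head_radius_range: tuple[float, float] = (10.0, 40.0)
    ccd_range: tuple[float, float] = (90.0, 160.0)
    torsion_range: tuple[float, float] = (-90.0, 90.0)
    isthmus_station_step: float = 1.0
    allow_heuristic_landmarks: bool = False


@dataclass
class FemurMeasurement:
    """The per-bone result row: both headline angles plus context and QC."""

    neck_shaft_angle: float
    torsion: float
    retroverted: bool
    bone_length: float
    head_radius: float
    isthmus_area: float
    qc_flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "neck_shaft_angle_deg": self.neck_shaft_angle,
            "torsion_deg": self.torsion,
            "retroverted": self.retroverted,
            "bone_length_mm": self.bone_length,
            "head_radius_mm": self.head_radius,
            "isthmus_area_mm2": self.isthmus_area,
            "qc_flags": ";".join(self.qc_flags),
            **self.meta,
        }


def neck_shaft_angle(axes: FemoralAxes) -> float:
    """Full 3D angle between neck direction (isthmus→head) and shaft
    direction (proximal→distal), degrees."""
    return angle_deg(axes.neck_axis.direction, axes.shaft_axis.direction)


def femoral_torsion(axes: FemoralAxes) -> float:
    """Signed femoral torsion (anteversion), degrees.

    Magnitude: acute angle between the neck axis projected onto the
    transversal plane and the posterior condylar tangent. Sign: positive when
    the projected head end lies anterior of the condylar line.
    """
    proj = project_direction_onto_plane(axes.neck_axis.direction, axes.transversal)
    magnitude = angle_deg(proj, axes.condylar_line.direction, acute=True)
    anterior = axes.frontal.normal  # oriented anterior by construction
    sign = 1.0 if proj @ anterior >= 0 else -1.0
    return sign * magnitude


def classify_retroversion(torsion: float) -> bool:
    """Retroverted iff the signed torsion is strictly negative (a neck
    pointing exactly along the condylar line is not retroverted)."""
    if not np.isfinite(torsion):
        raise ValueError("torsion must be finite")
    return bool(torsion < 0)


def extract_axes(bone: BoneModel, config: MeasureConfig | None = None) -> tuple[FemoralAxes, list[str]]:
    """Run the landmark/axis chain on a (left-oriented) bone.

    Returns the axes frame and any QC flags raised by recoverable sanity-gate
    violations. Unrecoverable geometry failures raise MeasurementError naming
    the stage.
    """
    cfg = config or MeasureConfig()
    qc: list[str] = []
    heur = cfg.allow_heuristic_landmarks

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except MeasurementError:
            raise
        except Exception as e:  # noqa: BLE001 - annotate with the stage name
            raise MeasurementError(f"{name}: {e}") from e

    length = stage("bone_length", ax.bone_length, bone, allow_heuristics=heur)
    shaft = stage("proximal_shaft_axis", ax.proximal_shaft_axis, bone, allow_heuristics=heur)
    head_center, head_radius, head_rms = stage(
        "femoral_head_center",
        ax.femoral_head_center,
        bone,
        shaft_axis=shaft,
        rms_gate=cfg.head_rms_gate,
        radius_range=cfg.head_radius_range,
    )
    if not cfg.head_radius_range[0] < head_radius < cfg.head_radius_range[1]:
        qc.append(f"head_radius_out_of_range:{head_radius:.1f}")
    isth = stage(
        "neck_isthmus",
        ax.neck_isthmus,
        bone,
        head_center,
        shaft,
        head_radius=head_radius,
        station_step=cfg.isthmus_station_step,
    )
    qc.extend(isth.flags)
    neck = stage("neck_axis", ax.neck_axis, head_center, isth.centroid)
    condylar = stage(
        "condylar_tangent_line",
        ax.condylar_tangent_line,
        bone,
        shaft.direction,
        allow_heuristics=heur,
    )
    anterior_hint = -condylar.posterior
    frontal, transversal = stage(
        "reference_planes", ax.reference_planes, shaft, condylar.line, anterior_hint
    )
    axes = FemoralAxes(
        shaft_axis=shaft,
        neck_axis=neck,
        head_center=head_center,
        head_radius=head_radius,
        isthmus_centroid=isth.centroid,
        isthmus_area=isth.area,
        condylar_line=condylar.line,
        frontal=frontal,
        transversal=transversal,
        bone_length=length,
    )
    return axes, qc


def measure_femur(bone: BoneModel, config: MeasureConfig | None = None) -> FemurMeasurement:
    """Measure one femur end to end.

    Right-side bones are mirrored to the left-femur convention first, so one
    sign convention serves both sides. Sanity-gate violations are recorded in
    ``qc_flags``; unrecoverable geometry errors propagate with the stage name.
    """
    cfg = config or MeasureConfig()
    if bone.side == "right":
        bone = bone.mirrored()
    axes, qc = extract_axes(bone, cfg)
    ccd = neck_shaft_angle(axes)
    torsion = femoral_torsion(axes)
    if not cfg.ccd_range[0] < ccd < cfg.ccd_range[1]:
        qc.append(f"ccd_out_of_range:{ccd:.1f}")
    if not cfg.torsion_range[0] < torsion <= cfg.torsion_range[1]:
        qc.append(f"torsion_out_of_range:{torsion:.1f}")
    return FemurMeasurement(
        neck_shaft_angle=float(ccd),
        torsion=float(torsion),
        retroverted=classify_retroversion(torsion),
        bone_length=float(axes.bone_length),
        head_radius=float(axes.head_radius),
        isthmus_area=float(axes.isthmus_area),
        qc_flags=qc,
        meta={"head_center": axes.head_center.tolist()},
    )
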