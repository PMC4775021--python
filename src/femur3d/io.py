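"""File formats and serialization: meshes, landmark sidecars, cohort tables.

Meshes are read with trimesh (STL binary/ASCII, PLY, OBJ); landmarks travel
in JSON sidecars; cohort tables are CSV or XLSX. The supplementary-style
raw-data reader is mapping-driven — per-study column layouts are described
by a column map rather than hard-coded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .angles import FemurMeasurement, MeasureConfig
from .axes import PATELLAR_SADDLE, TROCHANTER_TIP, BoneModel, MeasurementError
from .stats import GroupSummary, TestResult

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = (
    "id", "sex", "age", "bmi", "ethnicity", "side",
    "neck_shaft_angle_deg", "torsion_deg",
)

_SEX_VALUES = {
    "f": "female", "female": "female", "w": "female",
    "m": "male", "male": "male",
}
_ETHNICITY_VALUES = {
    "caucasian": "Caucasian", "asian": "Asian", "african": "African",
    "middleeastern": "MiddleEastern", "middle eastern": "MiddleEastern",
    "middle_eastern": "MiddleEastern",
}


class IOError_(MeasurementError):
    """Typed I/O failure (unreadable file, inconsistent bone model...)."""


@dataclass
class PipelineConfig:
    """Run configuration for the CLI pipeline (YAML-loadable)."""

    seed: int = 0
    output_dir: str = "femur3d_out"
    measure: MeasureConfig = field(default_factory=MeasureConfig)
    group_floor: int = 30
    column_map: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        measure = MeasureConfig(**raw.pop("measure", {}))
        return cls(measure=measure, **raw)


# ---------------------------------------------------------------------------
# bone models
# ---------------------------------------------------------------------------

def _load_mesh(path: str | Path) -> trimesh.Trimesh:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as e:  # noqa: BLE001
        raise IOError_(f"unreadable mesh file {path}: {e}") from e
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise IOError_(f"{path} does not contain a triangle mesh")
    # unit heuristic: adult femurs are hundreds of mm long; a sub-unit
    # bounding box means the file is in meters
    diag = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    if diag < 1.0:
        log.warning("read_bone_model: bbox diagonal %.3g < 1, rescaling m -> mm", diag)
        mesh.apply_scale(1000.0)
    return mesh


def read_landmarks(path: str | Path) -> tuple[dict[str, np.ndarray], str]:
    raw = json.loads(Path(path).read_text())
    side = raw.pop("side", "left")
    return {k: np.asarray(v, dtype=float) for k, v in raw.items() if k != "truth"}, side


def read_bone_model(
    outer_path: str | Path,
    inner_path: str | Path | None = None,
    landmarks_path: str | Path | None = None,
    side: str = "left",
    check_containment: bool = False,
) -> BoneModel:
    """Load a bone model from mesh files plus an optional landmark sidecar."""
    outer = _load_mesh(outer_path)
    inner = _load_mesh(inner_path) if inner_path else None
    landmarks: dict[str, np.ndarray] = {}
    if landmarks_path:
        landmarks, side = read_landmarks(landmarks_path)
    bone = BoneModel(outer=outer, inner=inner, landmarks=landmarks, side=side)
    if check_containment and inner is not None:
        frac = bone.inner_containment_fraction()
        if frac < 0.99:
            raise IOError_(
                f"inner surface not contained in outer ({frac:.0%} of sampled vertices inside)"
            )
    return bone


def write_bone_model(
    bone: BoneModel,
    outer_path: str | Path,
    inner_path: str | Path | None = None,
    landmarks_path: str | Path | None = None,
    truth: dict | None = None,
) -> None:
    """Write meshes (format from extension) and a JSON landmark sidecar."""
    bone.outer.export(str(outer_path))
    if inner_path and bone.inner is not None:
        bone.inner.export(str(inner_path))
    if landmarks_path:
        payload: dict = {k: v.tolist() for k, v in bone.landmarks.items()}
        payload["side"] = bone.side
        if truth:
            payload["truth"] = truth
        Path(landmarks_path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# measurement and cohort tables
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements: dict[str, FemurMeasurement]) -> pd.DataFrame:
    rows = []
    for subject_id, m in measurements.items():
        row = {"id": subject_id, **m.to_dict()}
        row.pop("head_center", None)
        rows.append(row)
    return pd.DataFrame(rows)


def read_cohort_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read a cohort/raw-data table from CSV or XLSX into canonical columns.

    ``column_map`` maps canonical names (``id, sex, age, bmi, ethnicity,
    side, neck_shaft_angle_deg, torsion_deg``) to the source column names —
    supplementary raw-data files ship their own column legends, so the
    layout is configuration, not code. Unmapped canonical columns are taken
    verbatim when a column of that name exists. Sex and ethnicity labels are
    normalized (f/m, case-insensitive ethnicities).
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"cohort table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path)
    column_map = column_map or {}
    out = pd.DataFrame()
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
    for required in ("sex", "neck_shaft_angle_deg", "torsion_deg"):
        if required not in out.columns:
            raise IOError_(
                f"cohort table lacks required column {required!r} "
                f"(source columns: {list(raw.columns)}; map: {column_map})"
            )
    out["sex"] = (
        out["sex"].astype(str).str.strip().str.lower().map(_SEX_VALUES)
    )
    if out["sex"].isna().any():
        raise IOError_("cohort table: unrecognized sex labels")
    if "ethnicity" in out.columns:
        out["ethnicity"] = (
            out["ethnicity"].astype(str).str.strip().str.lower().map(_ETHNICITY_VALUES)
        )
    for num in ("age", "bmi", "neck_shaft_angle_deg", "torsion_deg"):
        if num in out.columns:
            out[num] = pd.to_numeric(out[num], errors="coerce")
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def jsonable(obj):
    """Recursively convert report structures (GroupSummary, TestResult,
    numpy scalars) to plain JSON types."""
    if isinstance(obj, GroupSummary):
        return {k: jsonable(v) for k, v in obj._asdict().items()}
    if isinstance(obj, TestResult):
        return {k: jsonable(v) for k, v in obj._asdict().items()}
    if isinstance(obj, dict):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def table1_frame(report: dict) -> pd.DataFrame:
    """Flatten a subgroup_table report into a summary-table DataFrame with
    angles at 1-decimal reporting precision."""
    rows = []
    for group, cell in report["cells"].items():
        for angle, s in cell.items():
            rows.append(
                {
                    "group": group,
                    "angle": angle,
                    "n": s.n,
                    "median": round(s.median, 1),
                    "q1": round(s.q1, 1),
                    "q3": round(s.q3, 1),
                    "min": round(s.min, 1),
                    "max": round(s.max, 1),
                }
            )
    return pd.DataFrame(rows)


def write_report(report: dict, out_dir: str | Path, name: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{name}.json").write_text(json.dumps(jsonable(report), indent=1))
    if "cells" in report:
        table1_frame(report).to_csv(out_dir / f"{name}.csv", index=False)
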