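"""Parametric synthetic femurs with exactly known CCD and torsion angles.

The generator is the artifact's stand-in for segmented CT bone surfaces: a
left femur is assembled in a canonical frame (+z proximal, +x medial,
+y anterior) from implicit primitives —

* an outer shaft tube along the z axis, optionally bowed anteriorly distal
  to 40 % of bone length (so the proximal 25 %/35 % levels are provably
  straight),
* an hourglass neck tube whose axis makes exactly ``ccd_deg`` with the
  shaft axis and whose transversal projection makes exactly
  ``anteversion_deg`` with the condylar tangent (CCD is applied as the polar
  angle first, torsion as the azimuthal rotation second, so both ground
  truths are independent and analytic),
* a head sphere centered on the neck axis, a greater-trochanter prominence,
  and two posterior condylar spheres whose common posterior tangent is the
  condylar line, built mirror-symmetric so the tangent is exactly
  medio-lateral.

The signed-distance union of the primitives is sampled on a voxel grid and
the zero level set extracted with marching cubes, which yields a single
watertight, non-self-intersecting outer surface without needing a boolean
mesh engine. The medullary canal (inner cortical surface) is a separate
straight tube along the shaft. Exact landmarks (trochanter tip, facies
patellaris saddle) and the analytic ground-truth axes frame are emitted
alongside the meshes.

The cohort simulator draws per-subject true angles from the covariate
structure of a large adult left-femur population: torsion medians 16.4°
(female) / 12.1° (male) with residual spread ≈ 9°, CCD medians 123.0 /
121.5 with spread ≈ 5.8°, a mild decline of both angles with age, a weak
negative BMI–torsion association, and a Caucasian/Asian/African/Middle
Eastern ethnicity mix with a +1.3° Asian CCD offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from skimage import measure as _skmeasure

from .axes import PATELLAR_SADDLE, TROCHANTER_TIP, BoneModel, FemoralAxes
from .geometry import GeometryError, Line3, Plane, unit

__all__ = [
    "SyntheticFemurSpec",
    "CohortSpec",
    "ConstructiveGeometryError",
    "neck_direction",
    "generate_femur",
    "sample_cohort_truths",
    "generate_cohort",
]


class ConstructiveGeometryError(GeometryError):
    """The requested parameter combination yields self-intersecting anatomy."""


@dataclass(frozen=True)
class SyntheticFemurSpec:
    """All parameters of one parametric femur (mm / degrees)."""

    ccd_deg: float = 122.2
    anteversion_deg: float = 14.2
    bone_length_mm: float = 430.0
    head_radius_mm: float = 24.0
    neck_length_mm: float = 65.0
    neck_waist_radius_mm: float = 11.0
    shaft_outer_radius_mm: float = 13.5
    canal_radius_mm: float = 7.0
    condyle_radius_mm: float = 21.0
    condyle_separation_mm: float = 45.0
    shaft_bow_deg: float = 0.0
    mesh_subdivisions: int = 2  # refinement level: voxel = 2.0 / 2**(level-1) mm
    vertex_noise_sd_mm: float = 0.0
    seed: int = 0

    @property
    def voxel_mm(self) -> float:
        return 2.0 / 2 ** (self.mesh_subdivisions - 1)

    def validate(self) -> None:
        if not 90.0 < self.ccd_deg < 160.0:
            raise ConstructiveGeometryError(f"ccd_deg {self.ccd_deg} outside (90, 160)")
        if not -45.0 < self.anteversion_deg < 60.0:
            raise ConstructiveGeometryError(
                f"anteversion_deg {self.anteversion_deg} outside (-45, 60)"
            )
        for name in (
            "bone_length_mm", "head_radius_mm", "neck_length_mm",
            "neck_waist_radius_mm", "shaft_outer_radius_mm", "canal_radius_mm",
            "condyle_radius_mm", "condyle_separation_mm",
        ):
            if getattr(self, name) <= 0:
                raise ConstructiveGeometryError(f"{name} must be > 0")
        if self.neck_waist_radius_mm >= self.head_radius_mm:
            raise ConstructiveGeometryError("neck waist must be narrower than the head")
        if self.canal_radius_mm >= self.shaft_outer_radius_mm:
            raise ConstructiveGeometryError("canal must be narrower than the outer shaft")
        if self.neck_length_mm < self.head_radius_mm + 38.0:
            raise ConstructiveGeometryError(
                "neck too short: the isthmus would be swallowed by the head sphere"
            )


def neck_direction(ccd_deg: float, anteversion_deg: float) -> np.ndarray:
    """Unit neck-axis direction (isthmus → head) in the canonical frame.

    The polar angle from the proximal→distal shaft direction (0, 0, −1) is
    exactly ``ccd_deg``; the azimuth of the transversal projection, measured
    from the medio-lateral condylar direction (+x) toward anterior (+y), is
    exactly ``anteversion_deg``.
    """
    ccd = np.radians(ccd_deg)
    av = np.radians(anteversion_deg)
    return np.array(
        [np.sin(ccd) * np.cos(av), np.sin(ccd) * np.sin(av), -np.cos(ccd)]
    )


# ---------------------------------------------------------------------------
# implicit primitives
# ---------------------------------------------------------------------------

def _sphere_sdf(P: np.ndarray, center: np.ndarray, r: float) -> np.ndarray:
    return np.linalg.norm(P - center, axis=-1) - r


def _tube_sdf(P, base, direction, length, radius_of_s, y_offset_of_s=None):
    """Capped tube along ``direction`` with axially varying radius.

    ``radius_of_s`` maps the axial coordinate s ∈ [0, length] to a radius;
    ``y_offset_of_s`` optionally bends the centerline in +y (shaft bow).
    Approximate SDF (exact zero level set for slowly varying profiles).
    """
    d = P - base
    s = d @ direction
    sc = np.clip(s, 0.0, length)
    axis_pt = base + sc[..., None] * direction
    if y_offset_of_s is not None:
        axis_pt = axis_pt + np.outer(y_offset_of_s(sc), np.array([0.0, 1.0, 0.0])).reshape(
            axis_pt.shape
        )
    rho = np.linalg.norm(P - axis_pt, axis=-1)
    dx = rho - radius_of_s(sc)
    dz = np.abs(s - 0.5 * length) - 0.5 * length
    inside = np.minimum(np.maximum(dx, dz), 0.0)
    outside = np.sqrt(np.maximum(dx, 0.0) ** 2 + np.maximum(dz, 0.0) ** 2)
    return inside + outside


@dataclass
class _Primitive:
    sdf: object  # callable (..., 3) -> (...)
    aabb: np.ndarray  # (2, 3) min/max


def _mc_extract(prims: list[_Primitive], voxel: float) -> trimesh.Trimesh:
    """Sample the min-union of the primitives on a voxel grid and run
    marching cubes. The grid is aligned to integer multiples of the voxel
    size so mirror-symmetric primitive layouts stay exactly symmetric."""
    lo = np.min([p.aabb[0] for p in prims], axis=0) - 3.0 * voxel
    hi = np.max([p.aabb[1] for p in prims], axis=0) + 3.0 * voxel
    i0 = np.floor(lo / voxel).astype(int)
    i1 = np.ceil(hi / voxel).astype(int)
    shape = tuple(i1 - i0 + 1)
    coords = [voxel * np.arange(i0[k], i1[k] + 1) for k in range(3)]
    vol = np.full(shape, 4.0 * voxel, dtype=np.float32)
    for p in prims:
        j0 = np.maximum(np.floor(p.aabb[0] / voxel).astype(int) - 3, i0)
        j1 = np.minimum(np.ceil(p.aabb[1] / voxel).astype(int) + 3, i1)
        sl = tuple(slice(j0[k] - i0[k], j1[k] - i0[k] + 1) for k in range(3))
        X, Y, Z = np.meshgrid(
            coords[0][sl[0]], coords[1][sl[1]], coords[2][sl[2]], indexing="ij"
        )
        pts = np.stack([X, Y, Z], axis=-1)
        vol[sl] = np.minimum(vol[sl], p.sdf(pts).astype(np.float32))
    # grid nodes exactly on the surface would emit degenerate triangles;
    # nudge exact zeros inward (applied uniformly, so x-mirror symmetry holds)
    vol[vol == 0.0] = -1e-5 * voxel
    verts, faces, _, _ = _skmeasure.marching_cubes(vol, level=0.0, spacing=(voxel,) * 3)
    verts = verts + voxel * i0
    mesh = trimesh.Trimesh(vertices=verts.astype(float), faces=faces, process=True)
    return mesh


# ---------------------------------------------------------------------------
# femur construction
# ---------------------------------------------------------------------------

def _layout(spec: SyntheticFemurSpec) -> dict:
    """Derived canonical-frame geometry shared by mesh and ground truth."""
    L = spec.bone_length_mm
    n_dir = neck_direction(spec.ccd_deg, spec.anteversion_deg)
    neck_base = np.array([0.0, 0.0, 0.90 * L])
    head_center = neck_base + spec.neck_length_mm * n_dir
    waist_from_head = spec.head_radius_mm + 8.0  # isthmus clear of the head sphere
    s_waist = spec.neck_length_mm - waist_from_head
    isthmus = neck_base + s_waist * n_dir

    troch_r = 16.0
    troch_center = np.array([-28.0, 0.0, L - troch_r])
    tip = np.array([-28.0, 0.0, L])
    # saddle placed so that |tip - saddle| equals bone length exactly
    dz = np.sqrt(L**2 - 28.0**2 - 12.0**2)
    saddle = np.array([0.0, 12.0, L - dz])

    z_condyle = spec.condyle_radius_mm + 1.0
    condyle_y = -12.0
    z_bow_start = 0.60 * L  # bow confined distal to 40 % of length from the tip
    z_shaft_bot = max(2.0, z_condyle - 0.8 * spec.condyle_radius_mm)
    z_shaft_top = L - 8.0

    bow = np.radians(spec.shaft_bow_deg)

    def bow_offset(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        mask = z < z_bow_start
        span = z_bow_start - z_shaft_bot
        if bow != 0.0 and span > 0:
            out[mask] = np.tan(bow) / (2.0 * span) * (z_bow_start - z[mask]) ** 2
        return out

    cond_off = float(bow_offset(np.array([z_condyle]))[0])
    condyle_centers = [
        np.array([+0.5 * spec.condyle_separation_mm, condyle_y + cond_off, z_condyle]),
        np.array([-0.5 * spec.condyle_separation_mm, condyle_y + cond_off, z_condyle]),
    ]
    condylar_point = np.array(
        [0.0, condyle_y + cond_off - spec.condyle_radius_mm, z_condyle]
    )
    # head must stay clear of the trochanter prominence
    if np.linalg.norm(head_center - troch_center) < 0.9 * (spec.head_radius_mm + troch_r):
        raise ConstructiveGeometryError(
            "head sphere overlaps the greater trochanter at this CCD/torsion"
        )
    return dict(
        L=L, n_dir=n_dir, neck_base=neck_base, head_center=head_center,
        s_waist=s_waist, isthmus=isthmus, troch_center=troch_center,
        troch_r=troch_r, tip=tip, saddle=saddle,
        condyle_centers=condyle_centers, condylar_point=condylar_point,
        z_shaft_bot=z_shaft_bot, z_shaft_top=z_shaft_top, bow_offset=bow_offset,
        canal_z=(0.45 * L, 0.88 * L),
    )


def _ground_truth(spec: SyntheticFemurSpec, lay: dict) -> FemoralAxes:
    shaft = Line3(lay["neck_base"], np.array([0.0, 0.0, -1.0]))
    neck = Line3(lay["head_center"], lay["n_dir"])
    return FemoralAxes(
        shaft_axis=shaft,
        neck_axis=neck,
        head_center=lay["head_center"],
        head_radius=spec.head_radius_mm,
        isthmus_centroid=lay["isthmus"],
        isthmus_area=float(np.pi * spec.neck_waist_radius_mm**2),
        condylar_line=Line3(lay["condylar_point"], np.array([1.0, 0.0, 0.0])),
        frontal=Plane(lay["neck_base"], np.array([0.0, 1.0, 0.0])),
        transversal=Plane(lay["neck_base"], np.array([0.0, 0.0, -1.0])),
        bone_length=spec.bone_length_mm,
    )


def _neck_profile(spec: SyntheticFemurSpec, s_waist: float):
    """Hourglass radius profile along the neck: wide at the shaft junction,
    minimal at the waist, flaring toward the head (where the tube is
    swallowed by the head sphere)."""
    r_w = spec.neck_waist_radius_mm
    r_base = max(spec.shaft_outer_radius_mm + 0.5, r_w + 2.0)
    r_head = min(0.72 * spec.head_radius_mm, spec.head_radius_mm - 4.0)
    r_head = max(r_head, r_w + 1.0)
    length = spec.neck_length_mm

    def profile(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        r = np.empty_like(s)
        left = s <= s_waist
        r[left] = r_w + (r_base - r_w) * ((s_waist - s[left]) / s_waist) ** 2
        span = length - s_waist
        r[~left] = r_w + (r_head - r_w) * ((s[~left] - s_waist) / span) ** 2
        return r

    return profile


def ground_truth_axes(spec: SyntheticFemurSpec) -> FemoralAxes:
    """Analytic ground-truth axes frame for a spec, no meshing involved."""
    spec.validate()
    return _ground_truth(spec, _layout(spec))


def generate_femur(spec: SyntheticFemurSpec) -> tuple[BoneModel, FemoralAxes]:
    """Build one watertight synthetic left femur and its analytic ground truth.

    Deterministic given ``spec`` (including ``seed``, which drives only the
    optional vertex jitter).
    """
    spec.validate()
    lay = _layout(spec)
    voxel = spec.voxel_mm
    rs = spec.shaft_outer_radius_mm
    rh = spec.head_radius_mm
    rc = spec.condyle_radius_mm

    shaft_len = lay["z_shaft_top"] - lay["z_shaft_bot"]
    base_shaft = np.array([0.0, 0.0, lay["z_shaft_bot"]])
    zdir = np.array([0.0, 0.0, 1.0])
    bow_off = lay["bow_offset"]
    max_bow = float(bow_off(np.array([lay["z_shaft_bot"]]))[0])

    prims = [
        _Primitive(
            sdf=lambda P: _tube_sdf(
                P, base_shaft, zdir, shaft_len,
                lambda s: np.full_like(np.asarray(s, dtype=float), rs),
                y_offset_of_s=lambda s: bow_off(s + lay["z_shaft_bot"]),
            ),
            aabb=np.array(
                [[-rs, -rs, lay["z_shaft_bot"]],
                 [rs, rs + max_bow, lay["z_shaft_top"]]]
            ),
        ),
        _Primitive(
            sdf=lambda P: _tube_sdf(
                P, lay["neck_base"], lay["n_dir"], spec.neck_length_mm,
                _neck_profile(spec, lay["s_waist"]),
            ),
            aabb=np.array(
                [np.minimum(lay["neck_base"], lay["head_center"]) - 18.0,
                 np.maximum(lay["neck_base"], lay["head_center"]) + 18.0]
            ),
        ),
        _Primitive(
            sdf=lambda P: _sphere_sdf(P, lay["head_center"], rh),
            aabb=np.array([lay["head_center"] - rh, lay["head_center"] + rh]),
        ),
        _Primitive(
            sdf=lambda P: _sphere_sdf(P, lay["troch_center"], lay["troch_r"]),
            aabb=np.array(
                [lay["troch_center"] - lay["troch_r"], lay["troch_center"] + lay["troch_r"]]
            ),
        ),
    ]
    for c in lay["condyle_centers"]:
        prims.append(
            _Primitive(sdf=lambda P, c=c: _sphere_sdf(P, c, rc), aabb=np.array([c - rc, c + rc]))
        )

    outer = _mc_extract(prims, voxel)

    z0, z1 = lay["canal_z"]
    canal = trimesh.creation.cylinder(
        radius=spec.canal_radius_mm, height=z1 - z0, sections=48
    )
    canal.apply_translation([0.0, 0.0, 0.5 * (z0 + z1)])
    canal = trimesh.Trimesh(vertices=canal.vertices.copy(), faces=canal.faces.copy(), process=False)

    if spec.vertex_noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        outer.vertices += rng.normal(0.0, spec.vertex_noise_sd_mm, outer.vertices.shape)
        canal.vertices += rng.normal(0.0, spec.vertex_noise_sd_mm, canal.vertices.shape)

    bone = BoneModel(
        outer=outer,
        inner=canal,
        landmarks={TROCHANTER_TIP: lay["tip"], PATELLAR_SADDLE: lay["saddle"]},
        side="left",
    )
    return bone, _ground_truth(spec, lay)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Covariate structure of the simulated cohort.

    Defaults emulate a large adult left-femur CT population: 45 % female;
    torsion medians 16.4° (F) / 12.1° (M); CCD medians 123.0 / 121.5; a
    +1.3° Asian CCD offset; mild age declines (CCD ≈ −1.2°/decade, torsion
    ≈ −0.5°/decade around the reference age of 65); a weak negative
    BMI–torsion slope; log-normal BMI with median 25.7; ages clipped to
    19–109 with median ≈ 65.
    """

    n: int = 500
    sex_ratio_female: float = 0.45
    torsion_median: dict = field(
        default_factory=lambda: {"female": 16.4, "male": 12.1}
    )
    torsion_resid_sd: float = 8.9
    ccd_median: dict = field(default_factory=lambda: {"female": 123.0, "male": 121.5})
    ccd_resid_sd: float = 5.5
    ethnicity_mix: dict = field(
        default_factory=lambda: {
            "Caucasian": 0.757, "Asian": 0.203, "African": 0.025, "MiddleEastern": 0.015
        }
    )
    ccd_ethnicity_shift: dict = field(default_factory=lambda: {"Asian": 1.3})
    age_range: tuple[float, float] = (19.0, 109.0)
    age_mean: float = 64.0
    age_sd: float = 15.5
    age_reference: float = 65.0
    ccd_age_drift_per_decade: float = -1.2
    torsion_age_drift_per_decade: float = -0.5
    bmi_log_median: float = 25.7
    bmi_log_sigma: float = 0.168
    bmi_reference: float = 25.7
    torsion_bmi_slope: float = -0.15
    age_available: float = 0.92
    bmi_available: float = 0.747
    bone_length_mean: float = 432.0
    bone_length_sd: float = 22.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must be a probability")
        total = sum(self.ethnicity_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"ethnicity mix must sum to 1 (got {total})")


def sample_cohort_truths(cohort: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject covariates and true angles (no meshes).

    Deterministic given ``cohort.seed``. Ages/BMIs are always generated but
    masked to NaN per the availability fractions, mirroring real-cohort
    missingness; the masked values still drive the angle model, so complete
    and incomplete subjects follow one distribution.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n
    sex = np.where(rng.random(n) < cohort.sex_ratio_female, "female", "male")
    eth_names = list(cohort.ethnicity_mix)
    eth = rng.choice(eth_names, size=n, p=np.array([cohort.ethnicity_mix[e] for e in eth_names]))
    age = np.clip(rng.normal(cohort.age_mean, cohort.age_sd, n), *cohort.age_range)
    bmi = cohort.bmi_log_median * np.exp(rng.normal(0.0, cohort.bmi_log_sigma, n))

    ccd = (
        np.vectorize(cohort.ccd_median.get)(sex)
        + np.vectorize(lambda e: cohort.ccd_ethnicity_shift.get(e, 0.0))(eth)
        + cohort.ccd_age_drift_per_decade * (age - cohort.age_reference) / 10.0
        + rng.normal(0.0, cohort.ccd_resid_sd, n)
    )
    torsion = (
        np.vectorize(cohort.torsion_median.get)(sex)
        + cohort.torsion_age_drift_per_decade * (age - cohort.age_reference) / 10.0
        + cohort.torsion_bmi_slope * (bmi - cohort.bmi_reference)
        + rng.normal(0.0, cohort.torsion_resid_sd, n)
    )
    ccd = np.clip(ccd, 95.0, 155.0)
    torsion = np.clip(torsion, -40.0, 55.0)
    length = np.clip(
        rng.normal(cohort.bone_length_mean, cohort.bone_length_sd, n), 370.0, 510.0
    )
    age_mask = rng.random(n) < cohort.age_available
    bmi_mask = rng.random(n) < cohort.bmi_available
    return pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "sex": sex,
            "age": np.where(age_mask, np.round(age), np.nan),
            "bmi": np.where(bmi_mask, np.round(bmi, 1), np.nan),
            "ethnicity": eth,
            "side": "left",
            "true_ccd_deg": ccd,
            "true_torsion_deg": torsion,
            "bone_length_mm": length,
        }
    )


def generate_cohort(
    cohort: CohortSpec, build_meshes: bool = True
) -> tuple[list[BoneModel | None], pd.DataFrame]:
    """Simulate a cohort: truth table plus (optionally) one mesh per subject.

    Subjects whose parameter draw cannot be built (constructive-geometry
    error) are kept in the table with ``build_failed`` set and a None mesh.
    """
    truths = sample_cohort_truths(cohort)
    bones: list[BoneModel | None] = []
    failed = np.zeros(len(truths), dtype=bool)
    if build_meshes:
        child_seeds = np.random.SeedSequence(cohort.seed).generate_state(len(truths))
        for i, row in truths.iterrows():
            spec = SyntheticFemurSpec(
                ccd_deg=float(row.true_ccd_deg),
                anteversion_deg=float(row.true_torsion_deg),
                bone_length_mm=float(row.bone_length_mm),
                seed=int(child_seeds[i] % 2**31),
            )
            try:
                bone, _ = generate_femur(spec)
                bones.append(bone)
            except ConstructiveGeometryError:
                bones.append(None)
                failed[i] = True
    else:
        bones = [None] * len(truths)
    truths = truths.assign(build_failed=failed)
    return bones, truths
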