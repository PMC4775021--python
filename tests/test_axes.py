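"""Landmark/axis extraction: shaft axis, head sphere, isthmus, condyles."""

import numpy as np
import pytest
import trimesh

from femur3d import axes as ax
from femur3d.geometry import Line3, Plane, unit
from femur3d.synthetic import SyntheticFemurSpec, generate_femur
from .conftest import random_rotation, rigidly_transformed
from .oracles import geometric_sphere_fit


class TestLongitudinalDirectionAndLength:
    def test_canonical_femur_points_down(self, default_femur):
        bone, _ = default_femur
        d = ax.longitudinal_direction(bone)
        assert np.degrees(np.arccos(np.clip(-d[2], -1, 1))) < 2.0

    def test_rotation_equivariance(self, default_femur):
        bone, _ = default_femur
        rng = np.random.default_rng(0)
        R, t = random_rotation(rng), rng.normal(0, 100, 3)
        d0 = ax.longitudinal_direction(bone)
        d1 = ax.longitudinal_direction(rigidly_transformed(bone, R, t))
        assert np.linalg.norm(d1 - R @ d0) < 1e-6

    def test_degenerate_blob_warns(self, caplog):
        blob = trimesh.creation.icosphere(subdivisions=2, radius=30.0)
        bone = ax.BoneModel(outer=blob, landmarks={ax.TROCHANTER_TIP: [0, 0, 30.0]})
        with caplog.at_level("WARNING"):
            ax.longitudinal_direction(bone)
        assert any("aspect ratio" in r.message for r in caplog.records)

    def test_bone_length_from_landmarks(self):
        cube = trimesh.creation.box(extents=(10, 10, 10))
        bone = ax.BoneModel(
            outer=cube,
            landmarks={
                ax.TROCHANTER_TIP: [0, 0, 450.0],
                ax.PATELLAR_SADDLE: [0, 0, 0.0],
            },
        )
        assert ax.bone_length(bone) == pytest.approx(450.0)

    def test_bone_length_matches_generator_truth(self, default_femur):
        bone, truth = default_femur
        assert ax.bone_length(bone) == pytest.approx(truth.bone_length, abs=0.5)

    def test_missing_landmark_without_heuristics_raises(self):
        cube = trimesh.creation.box(extents=(10, 10, 10))
        bone = ax.BoneModel(outer=cube)
        with pytest.raises(ax.MeasurementError, match="landmark"):
            ax.bone_length(bone)

    def test_mirrored_bone_same_length(self, default_femur):
        bone, _ = default_femur
        assert ax.bone_length(bone.mirrored()) == pytest.approx(ax.bone_length(bone), abs=1e-9)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.5])
    def test_level_plane_fraction_bounds(self, default_femur, fraction):
        bone, _ = default_femur
        with pytest.raises(ValueError):
            ax.level_plane(bone, fraction)

    @pytest.mark.parametrize("fraction,expected", [(0.25, 107.5), (0.35, 150.5)])
    def test_level_plane_station_distance(self, default_femur, fraction, expected):
        bone, _ = default_femur
        plane = ax.level_plane(bone, fraction)
        tip = bone.landmarks[ax.TROCHANTER_TIP]
        assert abs(plane.signed_distance(tip)) == pytest.approx(expected, abs=1e-9)


class TestShaftAxis:
    def test_canal_midpoints_on_canal_axis(self, default_femur):
        bone, truth = default_femur
        for f in (0.25, 0.35):
            mid = ax.inner_cortical_midpoint(bone, f)
            # canal is a tube on the z axis
            assert np.linalg.norm(mid[:2]) < 1e-3

    def test_no_canal_at_level_raises_with_fraction(self, default_femur):
        bone, _ = default_femur
        with pytest.raises(ax.MeasurementError, match="95%"):
            ax.inner_cortical_midpoint(bone, 0.95)

    def test_missing_inner_mesh_raises(self, default_femur):
        bone, _ = default_femur
        no_inner = ax.BoneModel(outer=bone.outer, landmarks=bone.landmarks)
        with pytest.raises(ax.MeasurementError, match="inner"):
            ax.inner_cortical_midpoint(no_inner, 0.25)

    def test_recovers_generator_shaft_axis(self, default_femur):
        bone, truth = default_femur
        line = ax.proximal_shaft_axis(bone)
        ang = np.degrees(np.arccos(abs(np.clip(line.direction @ truth.shaft_axis.direction, -1, 1))))
        assert ang < 0.5
        assert line.direction @ truth.shaft_axis.direction > 0  # proximal→distal

    def test_bowed_shaft_leaves_proximal_axis_unaffected(self):
        bone, truth = generate_femur(SyntheticFemurSpec(shaft_bow_deg=6.0, seed=4))
        line = ax.proximal_shaft_axis(bone)
        ang = np.degrees(np.arccos(abs(np.clip(line.direction @ truth.shaft_axis.direction, -1, 1))))
        assert ang < 0.5


class TestHeadCenter:
    def test_recovers_head_sphere(self, default_femur):
        bone, truth = default_femur
        center, radius, rms = ax.femoral_head_center(bone)
        assert np.linalg.norm(center - truth.head_center) < 0.2
        assert abs(radius - truth.head_radius) < 0.2
        assert rms < 0.2

    def test_hint_far_outside_bone_raises(self, default_femur):
        bone, _ = default_femur
        with pytest.raises(ax.MeasurementError, match="hint"):
            ax.femoral_head_center(bone, hint=[500.0, 500.0, 500.0])

    def test_noisy_head_recovered_within_half_mm(self):
        bone, truth = generate_femur(SyntheticFemurSpec(vertex_noise_sd_mm=0.2, seed=9))
        center, radius, _ = ax.femoral_head_center(bone, rms_gate=1.0)
        assert np.linalg.norm(center - truth.head_center) < 0.5

    def test_center_error_monotone_in_noise(self):
        """Simulated head caps: recovery error shrinks to zero with noise."""
        rng = np.random.default_rng(42)
        true_c = np.array([50.0, 30.0, 400.0])
        errors = []
        for sd in (0.4, 0.2, 0.1, 0.0):
            errs = []
            for _ in range(20):
                v = rng.normal(size=(400, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                pts = true_c + 24.0 * v + rng.normal(0, sd, (400, 3))
                c, r = geometric_sphere_fit(pts)
                from femur3d.geometry import fit_sphere

                c_alg, _, _ = fit_sphere(pts)
                errs.append(np.linalg.norm(c_alg - true_c))
            errors.append(np.mean(errs))
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 1e-9


class TestIsthmusAndNeck:
    def test_isthmus_matches_generator_waist(self, default_femur):
        bone, truth = default_femur
        shaft = ax.proximal_shaft_axis(bone)
        center, radius, _ = ax.femoral_head_center(bone)
        res = ax.neck_isthmus(bone, center, shaft, head_radius=radius)
        assert res.area == pytest.approx(truth.isthmus_area, rel=0.03)
        assert np.linalg.norm(res.centroid - truth.isthmus_centroid) < 0.5
        assert res.n_iterations <= 20

    def test_cylindrical_neck_flags_flat_minimum(self):
        # a plain tube has no waist: mid-station is returned, flagged
        tube = trimesh.creation.cylinder(radius=11.0, height=80.0, sections=64)
        tube.apply_transform(
            trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])
        )  # axis now +x, spans x in [-40, 40]
        bone = ax.BoneModel(outer=tube)
        shaft = Line3([-60.0, 0, 0], [0, 0, -1.0])
        res = ax.neck_isthmus(bone, head_center=np.array([60.0, 0, 0]), shaft_axis=shaft)
        assert "flat_minimum" in res.flags
        assert res.area == pytest.approx(np.pi * 11.0**2, rel=0.02)

    def test_neck_axis_orientation_and_errors(self):
        line = ax.neck_axis([10.0, 0, 0], [0.0, 0, 0])
        np.testing.assert_allclose(line.direction, [1, 0, 0], atol=1e-12)
        with pytest.raises(ax.MeasurementError):
            ax.neck_axis([1.0, 2, 3], [1.0, 2, 3])

    def test_neck_axis_matches_generator(self, default_femur):
        bone, truth = default_femur
        shaft = ax.proximal_shaft_axis(bone)
        center, radius, _ = ax.femoral_head_center(bone)
        res = ax.neck_isthmus(bone, center, shaft, head_radius=radius)
        line = ax.neck_axis(center, res.centroid)
        ang = np.degrees(np.arccos(np.clip(line.direction @ truth.neck_axis.direction, -1, 1)))
        assert ang < 1.0


class TestCondylarTangent:
    def test_recovers_mediolateral_tangent(self, default_femur):
        bone, truth = default_femur
        shaft = ax.proximal_shaft_axis(bone)
        res = ax.condylar_tangent_line(bone, shaft.direction)
        cosang = abs(np.clip(res.line.direction @ truth.condylar_line.direction, -1, 1))
        assert np.degrees(np.arccos(cosang)) < 1.0
        # symmetric condyles: tangent perpendicular to the sagittal normal (y)
        assert abs(res.line.direction @ np.array([0, 1.0, 0])) < np.sin(np.radians(1.0))
        # posterior hint points -y in the canonical frame
        assert res.posterior @ np.array([0, -1.0, 0]) > 0.9

    def test_single_condyle_raises(self):
        bone, _ = generate_femur(SyntheticFemurSpec(condyle_separation_mm=1.0, seed=5))
        shaft = ax.proximal_shaft_axis(bone)
        with pytest.raises(ax.MeasurementError, match="condyle"):
            ax.condylar_tangent_line(bone, shaft.direction)


class TestReferencePlanes:
    def test_canonical_frame_reproduced(self):
        shaft = Line3([0, 0, 400.0], [0, 0, -1.0])
        cond = Line3([0, -30.0, 20.0], [1.0, 0, 0])
        frontal, transversal = ax.reference_planes(shaft, cond, anterior_hint=[0, 1.0, 0])
        np.testing.assert_allclose(transversal.normal, [0, 0, -1.0], atol=1e-12)
        np.testing.assert_allclose(frontal.normal, [0, 1.0, 0], atol=1e-12)
        assert abs(frontal.normal @ transversal.normal) < 1e-12

    def test_parallel_inputs_rejected(self):
        shaft = Line3([0, 0, 0], [0, 0, 1.0])
        with pytest.raises(Exception):
            ax.reference_planes(shaft, Line3([1, 0, 0], [0, 0, 1.0]), [0, 1.0, 0])

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(8)
        shaft = Line3([0, 0, 400.0], [0, 0, -1.0])
        cond = Line3([0, -30.0, 20.0], unit([1.0, 0.1, 0]))
        f0, t0 = ax.reference_planes(shaft, cond, [0, 1.0, 0])
        R, t = random_rotation(rng), rng.normal(0, 50, 3)
        f1, t1 = ax.reference_planes(
            Line3(R @ shaft.origin + t, R @ shaft.direction),
            Line3(R @ cond.origin + t, R @ cond.direction),
            R @ np.array([0, 1.0, 0]),
        )
        np.testing.assert_allclose(f1.normal, R @ f0.normal, atol=1e-9)
        np.testing.assert_allclose(t1.normal, R @ t0.normal, atol=1e-9)


class TestBoneModelValidation:
    def test_inner_contained_in_outer(self, default_femur):
        bone, _ = default_femur
        assert bone.inner_containment_fraction() >= 0.99

    def test_invalid_side_rejected(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        with pytest.raises(ValueError):
            ax.BoneModel(outer=cube, side="middle")
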