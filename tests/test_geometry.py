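"""Geometric kernel: sphere fit, sectioning, contours, angles."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from femur3d.geometry import (
    DegenerateInputError,
    GeometryError,
    Plane,
    PlanarContour,
    angle_deg,
    contour_centroid_area,
    fit_sphere,
    project_direction_onto_plane,
    section_mesh,
    signed_angle_in_plane,
    unit,
)
from .conftest import random_rotation
from .oracles import geometric_sphere_fit


def sphere_points(center, radius, n, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v


class TestFitSphere:
    def test_exact_on_axis_aligned_points(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        center, radius, rms = fit_sphere(pts)
        np.testing.assert_allclose(center, 0.0, atol=1e-12)
        assert radius == pytest.approx(1.0, abs=1e-12)
        assert rms < 1e-12

    def test_noiseless_samples_recovered_to_1e9(self):
        rng = np.random.default_rng(7)
        true_c = np.array([10.0, -3.0, 40.0])
        pts = sphere_points(true_c, 24.0, 200, rng)
        center, radius, _ = fit_sphere(pts)
        assert np.linalg.norm(center - true_c) < 1e-9
        assert abs(radius - 24.0) < 1e-9

    def test_noisy_fit_matches_geometric_oracle(self):
        rng = np.random.default_rng(11)
        true_c = np.array([10.0, -3.0, 40.0])
        pts = sphere_points(true_c, 24.0, 500, rng) + rng.normal(0, 0.1, (500, 3))
        center, radius, _ = fit_sphere(pts)
        oc, orr = geometric_sphere_fit(pts)
        assert np.linalg.norm(center - true_c) < 0.05
        assert np.linalg.norm(center - oc) < 0.02
        assert abs(radius - orr) < 0.02

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(DegenerateInputError):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_sphere(np.zeros((3, 3)))


class TestSectionMesh:
    def test_unit_cube_mid_section_is_unit_square(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        cube.apply_translation([0.5, 0.5, 0.5])
        contours = section_mesh(cube, Plane([0, 0, 0.5], [0, 0, 1]))
        assert len(contours) == 1
        centroid, area = contour_centroid_area(contours[0])
        assert area == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(centroid, [0.5, 0.5, 0.5], atol=1e-9)

    def test_icosphere_equator_area_matches_circle(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=24.0)
        contours = section_mesh(sph, Plane([0, 0, 0], [0, 0, 1]))
        assert len(contours) == 1
        _, area = contour_centroid_area(contours[0])
        assert area == pytest.approx(np.pi * 24.0**2, rel=0.005)

    def test_missing_plane_gives_empty_list(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        assert section_mesh(cube, Plane([0, 0, 99.0], [0, 0, 1])) == []

    def test_plane_through_cube_vertices_still_sections(self):
        # plane exactly at the cube's top face: coincident-face handling
        cube = trimesh.creation.box(extents=(1, 1, 1))
        contours = section_mesh(cube, Plane([0, 0, 0.5], [0, 0, 1]))
        # nudged section must still be a ~unit square (or legitimately empty
        # contact); sections strictly inside always work
        inner = section_mesh(cube, Plane([0, 0, 0.49999], [0, 0, 1]))
        assert len(inner) == 1

    def test_two_component_mesh_gives_two_contours(self):
        a = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        b = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        b.apply_translation([20.0, 0, 0])
        soup = trimesh.util.concatenate([a, b])
        contours = section_mesh(soup, Plane([0, 0, 0], [0, 0, 1]))
        assert len(contours) == 2

    def test_rigid_equivariance_of_section_areas(self):
        rng = np.random.default_rng(3)
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        plane = Plane([0, 0, 3.0], [0, 0, 1])
        _, area0 = contour_centroid_area(section_mesh(sph, plane)[0])
        for _ in range(5):
            R, t = random_rotation(rng), rng.normal(0, 50, 3)
            moved = trimesh.Trimesh(vertices=sph.vertices @ R.T + t, faces=sph.faces)
            mplane = Plane(R @ np.array([0, 0, 3.0]) + t, R @ np.array([0, 0, 1.0]))
            _, area = contour_centroid_area(section_mesh(moved, mplane)[0])
            assert area == pytest.approx(area0, rel=1e-6)


class TestContourCentroidArea:
    def test_unit_square(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        sq = PlanarContour(plane, [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        centroid, area = contour_centroid_area(sq)
        assert area == pytest.approx(1.0)
        np.testing.assert_allclose(centroid, [0.5, 0.5, 0.0], atol=1e-12)

    def test_right_triangle_any_plane_orientation(self):
        # triangle with legs 4 and 3 embedded in a tilted plane
        n = unit([1.0, 2.0, 2.0])
        plane = Plane([5, -2, 7], n)
        u = unit(np.cross(n, [0, 0, 1.0]))
        v = np.cross(n, u)
        pts2 = np.array([[0, 0], [4, 0], [0, 3]], dtype=float)
        pts3 = plane.point + pts2[:, :1] * u + pts2[:, 1:] * v
        centroid, area = contour_centroid_area(PlanarContour(plane, pts3))
        assert area == pytest.approx(6.0, abs=1e-9)
        expected = plane.point + (4 / 3) * u + 1.0 * v
        np.testing.assert_allclose(centroid, expected, atol=1e-9)

    def test_64gon_approximates_circle(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th), np.zeros(64)])
        _, area = contour_centroid_area(PlanarContour(Plane([0, 0, 0], [0, 0, 1]), pts))
        assert area == pytest.approx(100 * np.pi, rel=0.002)

    def test_area_matches_shapely(self):
        rng = np.random.default_rng(5)
        th = np.sort(rng.uniform(0, 2 * np.pi, 12))
        r = rng.uniform(5, 10, 12)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(12)])
        _, area = contour_centroid_area(PlanarContour(Plane([0, 0, 0], [0, 0, 1]), pts))
        from shapely.geometry import Polygon

        assert area == pytest.approx(Polygon(pts[:, :2]).area, rel=1e-12)

    def test_self_intersecting_rejected(self):
        bow = PlanarContour(
            Plane([0, 0, 0], [0, 0, 1]), [[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0]]
        )
        with pytest.raises(GeometryError):
            contour_centroid_area(bow)


class TestAngles:
    @pytest.mark.parametrize(
        "u,v,acute,expected",
        [
            ([1, 0, 0], [1, 0, 0], False, 0.0),
            ([1, 0, 0], [-1, 0, 0], False, 180.0),
            ([1, 0, 0], [-1, 0, 0], True, 0.0),
            ([1, 0, 0], [np.cos(np.radians(20)), np.sin(np.radians(20)), 0], False, 20.0),
        ],
    )
    def test_angle_examples(self, u, v, acute, expected):
        assert angle_deg(u, v, acute=acute) == pytest.approx(expected, abs=1e-9)

    def test_projection_examples_and_errors(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        with pytest.raises(DegenerateInputError):
            project_direction_onto_plane([0, 0, 1], plane)
        np.testing.assert_allclose(
            project_direction_onto_plane(unit([1, 0, 1]), plane), [1, 0, 0], atol=1e-12
        )

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_projection_is_unit_and_orthogonal_to_normal(self, seed):
        rng = np.random.default_rng(seed)
        d = unit(rng.normal(size=3))
        n = unit(rng.normal(size=3))
        if abs(d @ n) > 0.999:
            return
        p = project_direction_onto_plane(d, Plane(rng.normal(size=3), n))
        assert abs(np.linalg.norm(p) - 1.0) < 1e-9
        assert abs(p @ n) < 1e-9

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_angle_symmetry_and_acute_bound(self, seed):
        rng = np.random.default_rng(seed)
        u, v = unit(rng.normal(size=3)), unit(rng.normal(size=3))
        assert angle_deg(u, v) == pytest.approx(angle_deg(v, u), abs=1e-9)
        assert angle_deg(u, v, acute=True) <= 90.0 + 1e-12

    @pytest.mark.parametrize(
        "u,v,expected",
        [([1, 0, 0], [0, 1, 0], 90.0), ([0, 1, 0], [1, 0, 0], -90.0), ([1, 0, 0], [1, 0, 0], 0.0)],
    )
    def test_signed_angle_examples(self, u, v, expected):
        assert signed_angle_in_plane(u, v, [0, 0, 1]) == pytest.approx(expected, abs=1e-9)

    def test_signed_angle_requires_in_plane_inputs(self):
        with pytest.raises(GeometryError):
            signed_angle_in_plane([0, 0, 1], [1, 0, 0], [0, 0, 1])
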