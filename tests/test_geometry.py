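"""Geometric primitives: fits, rotations, distances, mesh intersection."""
import numpy as np
import pytest
import trimesh
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from graspmorph.geometry import (
    RigidTransform,
    fit_cylinder,
    fit_sphere,
    meshes_interpenetrate,
    point_line_distance,
    points_in_mesh,
    rotation_zyx,
    rotation_zyx_batch,
)


class TestFitSphere:
    def test_octahedron_unit_sphere(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        s = fit_sphere(pts)
        assert np.allclose(s.center, 0, atol=1e-12)
        assert np.isclose(s.radius, 1.0)

    def test_exact_on_noiseless_samples(self, rng):
        center, radius = np.array([1.0, 2.0, 3.0]), 5.0
        d = rng.normal(size=(50, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        s = fit_sphere(center + radius * d)
        assert np.allclose(s.center, center, atol=1e-9)
        assert np.isclose(s.radius, radius, atol=1e-9)
        assert s.residual_rms < 1e-9

    def test_planar_circle_raises(self):
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        with pytest.raises(ValueError, match="coplanar|ill-conditioned"):
            fit_sphere(pts)


class TestFitCylinder:
    @staticmethod
    def _cylinder_points(rng, n=120, radius=2.0, length=10.0):
        theta = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-length / 2, length / 2, n)
        return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])

    def test_canonical_pose(self, rng):
        pts = self._cylinder_points(rng)
        c = fit_cylinder(pts, np.array([0.0, 0.1, 0.9]))
        assert np.isclose(abs(c.axis_direction[2]), 1.0, atol=1e-6)
        assert np.isclose(c.radius, 2.0, atol=1e-6)
        assert c.residual_rms < 1e-6

    def test_transformed_cylinder_recovered(self, rng):
        pts = self._cylinder_points(rng)
        rot = Rotation.from_rotvec([0.4, -0.3, 0.8]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 1.0])
        truth_axis = rot @ np.array([0.0, 0.0, 1.0])
        c = fit_cylinder(moved, truth_axis + rng.normal(scale=0.05, size=3))
        angle = np.arccos(np.clip(abs(c.axis_direction @ truth_axis), 0, 1))
        assert angle < 1e-4
        assert np.isclose(c.radius, 2.0, atol=1e-6)

    def test_noisy_radius_recovery(self):
        # Monte-Carlo over seeds: radius recovered within 0.05 under sigma=0.01 noise
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = self._cylinder_points(rng)
            pts += rng.normal(scale=0.01, size=pts.shape)
            c = fit_cylinder(pts, np.array([0.05, -0.02, 1.0]))
            assert abs(c.radius - 2.0) < 0.05

    def test_collinear_raises(self):
        pts = np.outer(np.linspace(0, 1, 10), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            fit_cylinder(pts, np.array([1.0, 1.0, 0.0]))


class TestRotationZYX:
    def test_identity(self):
        assert np.allclose(rotation_zyx(0, 0, 0).rotation, np.eye(3))

    def test_z90_maps_x_to_y(self):
        r = rotation_zyx(90, 0, 0).rotation
        assert np.allclose(r @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_matches_quaternion_composition(self, rng):
        # independent oracle: compose single-axis quaternions z * y * x
        for _ in range(50):
            z, y, x = rng.uniform(-180, 180, 3)
            q = (Rotation.from_rotvec(np.radians(z) * np.array([0, 0, 1]))
                 * Rotation.from_rotvec(np.radians(y) * np.array([0, 1, 0]))
                 * Rotation.from_rotvec(np.radians(x) * np.array([1, 0, 0])))
            assert np.allclose(rotation_zyx(z, y, x).rotation, q.as_matrix(), atol=1e-12)

    def test_batch_matches_scalar_and_is_orthonormal(self, rng):
        angles = rng.uniform(-180, 180, (200, 3))
        batch = rotation_zyx_batch(angles)
        for i in (0, 57, 199):
            assert np.allclose(batch[i], rotation_zyx(*angles[i]).rotation, atol=1e-12)
        eye = np.einsum("nij,nkj->nik", batch, batch)
        assert np.allclose(eye, np.eye(3), atol=1e-12)
        assert np.allclose(np.linalg.det(batch), 1.0, atol=1e-12)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            rotation_zyx(np.nan, 0, 0)


class TestPointLineDistance:
    def test_point_on_line(self):
        d, nearest = point_line_distance([2, 0, 0], [0, 0, 0], [1, 0, 0])
        assert d == 0
        assert np.allclose(nearest, [2, 0, 0])

    def test_unit_offset(self):
        d, nearest = point_line_distance([0, 1, 0], [0, 0, 0], [1, 0, 0])
        assert np.isclose(d, 1.0)
        assert np.allclose(nearest, [0, 0, 0])

    def test_matches_scalar_minimisation(self, rng):
        for _ in range(200):
            p, a, b = rng.normal(size=(3, 3)) * 10
            d, _ = point_line_distance(p, a, b)
            f = lambda t: np.linalg.norm(p - (a + t * (b - a)))
            res = minimize_scalar(f, bounds=(-1e3, 1e3), method="bounded",
                                  options={"xatol": 1e-12})
            assert abs(d - res.fun) < 1e-9

    def test_rigid_invariance(self, rng):
        p, a, b = rng.normal(size=(3, 3))
        d0, _ = point_line_distance(p, a, b)
        t = RigidTransform(Rotation.from_rotvec([0.3, 1.0, -0.2]).as_matrix(), np.array([4.0, 5, 6]))
        d1, _ = point_line_distance(t.apply(p), t.apply(a), t.apply(b))
        assert abs(d0 - d1) < 1e-9

    def test_coincident_endpoints_raise(self):
        with pytest.raises(ValueError):
            point_line_distance([0, 1, 0], [1, 1, 1], [1, 1, 1])


def _cube(center, side=1.0):
    m = trimesh.creation.box(extents=(side, side, side))
    m.apply_translation(center)
    return m


class TestMeshInterpenetration:
    def test_separated_cubes(self):
        assert meshes_interpenetrate(_cube([0, 0, 0]), _cube([3, 0, 0])) is False

    def test_overlapping_cubes(self):
        assert meshes_interpenetrate(_cube([0, 0, 0]), _cube([0.5, 0, 0])) is True

    def test_contained_cube_no_surface_crossing(self):
        assert meshes_interpenetrate(_cube([0, 0, 0]), _cube([0.1, 0, 0], side=0.1)) is True

    def test_symmetry(self):
        a, b = _cube([0, 0, 0]), _cube([0.8, 0.3, 0.2])
        assert meshes_interpenetrate(a, b) == meshes_interpenetrate(b, a)

    def test_crossing_without_contained_vertices(self):
        # plus-sign: two long thin boxes crossing; all vertices outside both
        a = trimesh.creation.box(extents=(10, 0.5, 0.5))
        b = trimesh.creation.box(extents=(0.5, 10, 0.5))
        assert meshes_interpenetrate(a, b) is True

    def test_non_watertight_raises_with_name(self):
        a = _cube([0, 0, 0])
        broken = trimesh.Trimesh(vertices=a.vertices, faces=a.faces[:-2], process=False)
        with pytest.raises(ValueError, match="distal"):
            meshes_interpenetrate(a, broken, names=("proximal", "distal"))

    def test_points_in_mesh_parity(self, rng):
        cube = _cube([0, 0, 0], side=2.0)
        pts = rng.uniform(-2, 2, size=(200, 3))
        expected = np.all(np.abs(pts) < 1.0, axis=1)
        assert np.array_equal(points_in_mesh(cube, pts), expected)
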