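"""Cosine correction, critical alpha, alpha-shape volumes, excursions."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from graspmorph.posespace import (
    alpha_shape,
    cosine_correct,
    critical_alpha,
    excursion_summary,
    pose_space_shape,
    select_alpha,
)


class TestCosineCorrect:
    def test_origin_fixed(self):
        assert np.allclose(cosine_correct([(0, 0, 0)]).points, 0)

    def test_cos60_halves_z(self):
        out = cosine_correct([(100, 60, 10)]).points[0]
        assert np.allclose(out, [50, 60, 10])

    def test_y90_kills_z(self):
        for z in (-170, 30, 100):
            out = cosine_correct([(z, 90, 7)]).points[0]
            assert abs(out[0]) < 1e-10 and out[1] == 90 and out[2] == 7

    def test_beyond_gimbal_raises(self):
        with pytest.raises(ValueError):
            cosine_correct([(0, 95, 0)])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(-180, 180), st.floats(-90, 90), st.floats(-180, 180))
    def test_preserves_yx_and_shrinks_z(self, z, y, x):
        out = cosine_correct([(z, y, x)]).points[0]
        assert out[1] == y and out[2] == x
        assert abs(out[0]) <= abs(z) + 1e-12

    def test_haar_uniformity_after_correction(self):
        # rotations sampled uniformly from SO(3), decomposed as intrinsic
        # z-y-x angles and cosine-corrected, are uniform in (zcc, ycc)
        for seed in (0, 1):
            rot = Rotation.random(10000, rng=np.random.default_rng(seed))
            zyx = rot.as_euler("ZYX", degrees=True)
            cc = cosine_correct(zyx).points
            sel = cc[(np.abs(cc[:, 1]) <= 60) & (np.abs(cc[:, 0]) <= 80)]
            h, _, _ = np.histogram2d(sel[:, 0], sel[:, 1], bins=[6, 6],
                                     range=[[-80, 80], [-60, 60]])
            _, p = chisquare(h.ravel())
            assert p > 0.01


class TestCriticalAlpha:
    def test_regular_tetrahedron_circumradius(self):
        a = 10.0
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        tet *= a / np.sqrt(8)
        assert np.isclose(critical_alpha(tet), a * np.sqrt(3.0 / 8.0), atol=1e-9)

    def test_two_far_clusters_need_bridging_alpha(self, rng):
        c1 = rng.uniform(0, 2, (30, 3))
        c2 = c1 + [104.0, 0, 0]  # >=100 gap between the clusters
        crit = critical_alpha(np.vstack([c1, c2]))
        assert crit >= 50.0
        # brute force: below the critical alpha no tetrahedron bridges the
        # clusters, so the shape cannot be a single region
        shape = alpha_shape(np.vstack([c1, c2]), crit * 0.5)
        in_first = shape.simplices < 30
        assert np.all(in_first.all(axis=1) | (~in_first).all(axis=1))

    def test_bounded_by_max_circumradius(self, rng):
        pts = rng.uniform(0, 20, (80, 3))
        tri_alpha = critical_alpha(pts)
        assert alpha_shape(pts, tri_alpha).volume > 0

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            critical_alpha(np.zeros((3, 3)))


class TestSelectAlpha:
    def test_floor_applies(self, rng):
        pts = rng.uniform(0, 10, (100, 3))  # dense cloud: small critical alpha
        assert select_alpha(pts, floor=50.0) == 50.0

    def test_critical_above_floor_wins(self, rng):
        c1 = rng.uniform(0, 2, (30, 3))
        c2 = c1 + [104.0, 0, 0]
        pts = np.vstack([c1, c2])
        crit = critical_alpha(pts)
        assert crit > 50.0
        assert select_alpha(pts, floor=50.0) == crit


class TestAlphaShape:
    def test_cube_corners_hull_volume(self):
        cube = np.array([[x, y, z] for x in (0, 10) for y in (0, 10) for z in (0, 10)], float)
        assert np.isclose(alpha_shape(cube, 1e6).volume, 1000.0)

    def test_three_points_raise(self):
        with pytest.raises(ValueError):
            alpha_shape(np.eye(3), 10.0)

    def test_separated_clusters_sum_of_hulls(self, rng):
        c1 = rng.uniform(0, 5, (60, 3))
        c2 = rng.uniform(0, 5, (60, 3)) + [50.0, 0, 0]
        vol = alpha_shape(np.vstack([c1, c2]), 10.0).volume
        expected = ConvexHull(c1).volume + ConvexHull(c2).volume
        assert abs(vol - expected) / expected < 0.05

    def test_volume_monotone_in_alpha_and_hull_limit(self, rng):
        pts = rng.uniform(0, 15, (120, 3))
        alphas = [2.0, 4.0, 8.0, 16.0, 1e6]
        vols = [alpha_shape(pts, a).volume for a in alphas]
        assert all(v1 <= v2 + 1e-9 for v1, v2 in zip(vols, vols[1:]))
        assert np.isclose(vols[-1], ConvexHull(pts).volume, atol=1e-6)

    def test_coplanar_cloud_warns_zero_volume(self, rng):
        pts = np.column_stack([rng.uniform(0, 5, (20, 2)), np.zeros(20)])
        with pytest.warns(UserWarning, match="coplanar"):
            res = alpha_shape(pts, 50.0)
        assert res.volume == 0.0

    def test_cosine_corrected_box_matches_integral(self):
        # analytic box of poses: alpha volume of the corrected cloud must
        # match the closed-form integral of cos(y) dz dy dx
        z = np.arange(-60, 61, 5.0)
        y = np.arange(-40, 41, 5.0)
        x = np.arange(-20, 21, 5.0)
        box = np.array([[zz, yy, xx] for zz in z for yy in y for xx in x])
        res = pose_space_shape(cosine_correct(box), floor=50.0)
        y0, y1 = np.radians(-40), np.radians(40)
        analytic = 120.0 * 40.0 * np.degrees(np.sin(y1) - np.sin(y0))
        assert abs(res.volume - analytic) / analytic < 0.05


class TestExcursionSummary:
    def test_single_point(self):
        e = excursion_summary(np.array([[5.0, -10.0, 20.0]]))
        assert (e.fe_min, e.fe_max) == (5, 5)
        assert (e.abad_min, e.abad_max) == (-10, -10)
        assert (e.ie_min, e.ie_max) == (20, 20)

    def test_two_points(self):
        e = excursion_summary(np.array([[0.0, 0, 0], [10.0, -20, 30]]))
        assert (e.fe_min, e.fe_max, e.abad_min, e.abad_max, e.ie_min, e.ie_max) == \
            (0, 10, -20, 0, 0, 30)

    def test_matches_linear_scan(self, rng):
        pts = rng.normal(size=(500, 3))
        e = excursion_summary(pts)
        assert e.fe_min == pts[:, 0].min() and e.ie_max == pts[:, 2].max()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            excursion_summary(np.empty((0, 3)))
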