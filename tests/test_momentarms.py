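"""Moment arms: point-line oracle equivalence, scaling, normalisation."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from graspmorph.geometry import Frame, RigidTransform
from graspmorph.momentarms import (
    MusclePath,
    ScaleFactor,
    imma_at_pose,
    imma_field,
    normalize_imma,
    scale_imma,
)
from graspmorph.posespace import cosine_correct
from graspmorph.rig import (
    Convention,
    JointModel,
    PoseViabilityTable,
    generate_pose_grid,
    sweep,
)
from graspmorph.synthetic import make_muscle_fixture


def _viability_table(poses):
    df = pd.DataFrame(poses, columns=["z_deg", "y_deg", "x_deg"])
    df["code"] = 1
    df["disarticulated"] = False
    return PoseViabilityTable(df)


class TestImmaAtPose:
    def test_through_cor_is_zero(self, ball_socket_small):
        model, _, _ = ball_socket_small
        muscle, analytic, _ = make_muscle_fixture("through_cor")
        for pose in [(0, 0, 0), (30, -10, 5), (-60, 45, 80)]:
            assert imma_at_pose(model, muscle, pose) == analytic(pose) == 0.0

    def test_parallel_line_at_reference(self, ball_socket_small):
        model, _, _ = ball_socket_small
        muscle = MusclePath("m", np.array([10.0, 0, 0]), np.array([10.0, 5, 0]))
        assert np.isclose(imma_at_pose(model, muscle, (0, 0, 0)), 10.0)

    def test_perpendicular_fixture_at_reference(self, ball_socket_small):
        model, _, _ = ball_socket_small
        muscle, analytic, params = make_muscle_fixture("perpendicular_at_d", {"d": 7.0})
        assert abs(imma_at_pose(model, muscle, (0, 0, 0)) - 7.0) < 1e-9

    def test_matches_brute_force_oracle(self, ball_socket_small, rng):
        # oracle: cross-product point-to-line distance evaluated directly on
        # the transformed attachment points
        model, _, _ = ball_socket_small
        for _ in range(200):
            origin = rng.normal(scale=20, size=3)
            insertion = rng.normal(scale=8, size=3)
            pose = rng.uniform(-120, 120, 3)
            muscle = MusclePath("m", origin, insertion)
            got = imma_at_pose(model, muscle, pose)
            w = model.world_rotation(pose)
            ins = model.cor + w @ (insertion - model.cor)
            ab = ins - origin
            expect = np.linalg.norm(np.cross(model.cor - origin, ab)) / np.linalg.norm(ab)
            assert abs(got - expect) < 1e-9

    def test_rigid_invariance(self, rng):
        # moving model + muscle by one rigid transform leaves the IMMA alone
        rot = Rotation.from_rotvec([0.2, 0.9, -0.4]).as_matrix()
        shift = np.array([3.0, -7.0, 11.0])
        cor = np.array([1.0, 2.0, 3.0])
        import trimesh
        cube = trimesh.creation.box(extents=(1, 1, 1))
        base = JointModel(cube, cube.copy(), cor, Frame(cor, np.eye(3)), None,
                          Convention.PRIMATE_MARSUPIAL, RigidTransform.identity())
        moved = JointModel(cube, cube.copy(), rot @ cor + shift,
                           Frame(rot @ cor + shift, rot @ np.eye(3)), None,
                           Convention.PRIMATE_MARSUPIAL, RigidTransform.identity())
        for _ in range(20):
            origin = rng.normal(size=3) * 10
            insertion = rng.normal(size=3) * 5
            pose = rng.uniform(-90, 90, 3)
            m0 = MusclePath("m", origin, insertion)
            m1 = MusclePath("m", rot @ origin + shift, rot @ insertion + shift)
            assert np.isclose(imma_at_pose(base, m0, pose),
                              imma_at_pose(moved, m1, pose), atol=1e-9)

    def test_bounded_by_insertion_radius(self, ball_socket_small, rng):
        model, _, _ = ball_socket_small
        r = 6.0
        insertion = model.cor + np.array([r, 0, 0])
        muscle = MusclePath("m", np.array([0.0, 500.0, 0.0]), insertion)
        for pose in rng.uniform(-120, 120, size=(50, 3)):
            assert imma_at_pose(model, muscle, pose) <= r + 1e-9


class TestScaling:
    def test_worked_ratio(self):
        assert scale_imma(2.0, ScaleFactor(30.0, 15.0)) == 4.0

    def test_identity_when_equal(self):
        assert scale_imma(1.234, ScaleFactor(7.0, 7.0)) == 1.234

    def test_random_matches_formula(self, rng):
        for _ in range(50):
            v, a, b = rng.uniform(0.1, 10, 3)
            assert np.isclose(scale_imma(v, ScaleFactor(a, b)), a / b * v)

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError):
            ScaleFactor(1.0, 0.0)


class TestNormalisation:
    def test_basic(self):
        assert normalize_imma(3.0, 30.0) == 0.1

    def test_zero_imma(self):
        assert normalize_imma(0.0, 12.0) == 0.0

    def test_scale_invariance(self, rng):
        for _ in range(20):
            imma, length = rng.uniform(0.1, 20, 2)
            assert np.isclose(normalize_imma(imma, length),
                              normalize_imma(2 * imma, 2 * length))

    def test_nonpositive_length_raises(self):
        with pytest.raises(ValueError):
            normalize_imma(1.0, 0.0)


class TestImmaField:
    def test_single_viable_pose(self, ball_socket_small):
        model, _, _ = ball_socket_small
        muscle, _, _ = make_muscle_fixture("perpendicular_at_d", {"d": 4.0})
        table = _viability_table([[0.0, 0.0, 0.0]])
        records, argmax = imma_field(model, muscle, table, ScaleFactor(1, 1))
        assert len(records) == 1
        assert np.allclose(argmax, [[0, 0, 0]])

    def test_planar_cosine_argmax_near_analytic_optimum(self, ball_socket_small):
        model, _, _ = ball_socket_small
        muscle, analytic, params = make_muscle_fixture("planar_cosine")
        zs = np.arange(-135, 140, 5.0)
        table = _viability_table([[z, 0.0, 0.0] for z in zs])
        records, argmax = imma_field(model, muscle, table, ScaleFactor(1, 1))
        target = params["argmax_z_deg"]
        # the analytic optimum modulo the sampled range
        candidates = [target, target - 180.0, target + 180.0]
        best_z = argmax[0][0]
        assert min(abs(best_z - c) for c in candidates) <= 5.0

    def test_values_finite_nonnegative_and_joined(self, ball_socket_sweep, ball_socket_small):
        model, _, _ = ball_socket_small
        _, table = ball_socket_sweep
        muscle, _, _ = make_muscle_fixture("planar_cosine")
        cloud = cosine_correct(table.viable[["z_deg", "y_deg", "x_deg"]].to_numpy())
        records, _ = imma_field(model, muscle, table, ScaleFactor(25.0, 10.0), corrected=cloud)
        assert len(records) == table.n_viable
        assert np.all(np.isfinite(records["imma_norm"]))
        assert (records["imma_norm"] >= 0).all()
        assert {"zcc", "ycc", "xcc"} <= set(records.columns)
        assert np.allclose(records["imma_mm"], 2.5 * records["imma_model"])

    def test_no_viable_poses_raise(self, ball_socket_small):
        model, _, _ = ball_socket_small
        muscle, _, _ = make_muscle_fixture("through_cor")
        df = pd.DataFrame({"z_deg": [0.0], "y_deg": [0.0], "x_deg": [0.0],
                           "code": [0], "disarticulated": [False]})
        with pytest.raises(ValueError):
            imma_field(model, muscle, PoseViabilityTable(df), ScaleFactor(1, 1))
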