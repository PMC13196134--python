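"""Joint rig: pose grid, pose transforms, viability classification, sweep."""
import numpy as np
import pandas as pd
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from graspmorph.geometry import Frame, RigidTransform, Sphere
from graspmorph.rig import (
    Convention,
    JointModel,
    PoseViabilityTable,
    build_joint_model,
    check_inclusion,
    classify_pose,
    filter_disarticulated,
    generate_pose_grid,
    pose_transform,
    sweep,
)
from graspmorph.synthetic import BallSocketSpec, make_ball_and_socket, swing_angle_deg


class TestPoseGrid:
    def test_default_grid_size(self):
        grid = generate_pose_grid()
        assert len(grid) == 55 * 37 * 37 == 75295

    def test_coarse_grid(self):
        assert len(generate_pose_grid(180, 180, 180, 90)) == 27

    def test_contains_reference_pose(self):
        grid = generate_pose_grid(30, 20, 10, 5)
        assert any(np.allclose(p, 0) for p in grid.poses)

    def test_indivisible_range_raises(self):
        with pytest.raises(ValueError):
            generate_pose_grid(271, 180, 180, 5)


class TestPoseTransform:
    def test_reference_pose_is_reference_transform(self, ball_socket_small):
        model, _, _ = ball_socket_small
        t = pose_transform(model, (0, 0, 0))
        assert np.allclose(t.matrix, model.reference.matrix, atol=1e-12)

    def test_z90_rotates_about_world_z(self, ball_socket_small):
        model, _, _ = ball_socket_small
        t = pose_transform(model, (90, 0, 0))
        v = np.array([1.0, 0.0, 0.0])
        assert np.allclose(t.rotation @ v, [0, 1, 0], atol=1e-12)

    def test_distances_to_cor_preserved(self, ball_socket_small, rng):
        model, _, _ = ball_socket_small
        ref = model.reference.apply(model.distal.vertices[:50])
        d_ref = np.linalg.norm(ref - model.cor, axis=1)
        for pose in rng.uniform(-90, 90, size=(5, 3)):
            posed = pose_transform(model, pose).apply(model.distal.vertices[:50])
            assert np.allclose(np.linalg.norm(posed - model.cor, axis=1), d_ref, atol=1e-9)


class TestClassifyAndSweep:
    def test_reference_pose_viable(self, ball_socket_small):
        model, _, _ = ball_socket_small
        assert classify_pose(model, (0, 0, 0)) == 1

    def test_small_swing_viable_large_swing_not(self, ball_socket_small):
        model, predicate, _ = ball_socket_small
        assert predicate((10, 0, 0)) and classify_pose(model, (10, 0, 0)) == 1
        assert not predicate((50, 0, 0)) and classify_pose(model, (50, 0, 0)) == 0

    def test_sweep_matches_analytic_predicate(self, ball_socket_small, ball_socket_sweep):
        model, predicate, params = ball_socket_small
        grid, table = ball_socket_sweep
        codes = table.df["code"].to_numpy()
        analytic = np.array([predicate(p) for p in grid.poses], dtype=int)
        agreement = (codes == analytic).mean()
        assert agreement >= 0.95
        psi = swing_angle_deg(grid.poses)
        deviations = np.abs(psi[codes != analytic] - params["swing_limit_deg"])
        if deviations.size:
            assert deviations.max() <= grid.step  # disagreements hug the boundary

    def test_sweep_symmetric_under_ie(self, ball_socket_small, ball_socket_sweep):
        # revolution symmetry: viability independent of the x (IE) angle,
        # up to the seeded surface jitter, which can flip cells only at the
        # analytic viability boundary
        _, _, params = ball_socket_small
        grid, table = ball_socket_sweep
        df = table.df
        mixed = df.groupby(["z_deg", "y_deg"])["code"].nunique()
        frac = (mixed == 1).mean()
        assert frac >= 0.99
        if (mixed > 1).any():
            bad = np.array(mixed[mixed > 1].index.tolist(), dtype=float)
            psi = swing_angle_deg(np.column_stack([bad, np.zeros(len(bad))]))
            assert np.all(np.abs(psi - params["swing_limit_deg"]) <= grid.step)

    def test_viability_invariant_under_joint_rigid_transform(self):
        model, _, _ = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=30.0, mesh_resolution=700, seed=3))
        rot = Rotation.from_rotvec([0.7, -0.2, 0.4]).as_matrix()
        shift = np.array([10.0, -4.0, 2.0])
        t4 = np.eye(4)
        t4[:3, :3] = rot
        t4[:3, 3] = shift
        prox = model.proximal.copy()
        dist = model.distal.copy()
        prox.apply_transform(t4)
        dist.apply_transform(t4)
        moved = JointModel(
            proximal=prox, distal=dist, cor=rot @ model.cor + shift,
            jcs=Frame(rot @ model.cor + shift, rot @ model.jcs.axes),
            gap_sphere=model.gap_sphere, convention=model.convention,
            reference=RigidTransform(rot, shift).compose(model.reference).compose(
                RigidTransform(rot, shift).inverse()),
        )
        for pose in [(0, 0, 0), (15, 5, -10), (40, 0, 0), (0, 35, 0)]:
            assert classify_pose(model, pose) == classify_pose(moved, pose)


def _table(rows):
    df = pd.DataFrame(rows, columns=["z_deg", "y_deg", "x_deg", "code"])
    df["disarticulated"] = False
    return PoseViabilityTable(df)


class TestDisarticulationFilter:
    def test_positive_threshold(self):
        t = _table([[55, 0, 0, 1], [65, 0, 0, 1], [0, 0, 0, 1]])
        out = filter_disarticulated(t, z_positive_max=60)
        df = out.df.set_index("z_deg")
        assert df.loc[65, "code"] == 0 and df.loc[65, "disarticulated"]
        assert df.loc[55, "code"] == 1 and not df.loc[55, "disarticulated"]

    def test_negative_threshold(self):
        t = _table([[-60, 0, 0, 1], [-50, 0, 0, 1]])
        out = filter_disarticulated(t, z_negative_min=-55)
        df = out.df.set_index("z_deg")
        assert df.loc[-60, "code"] == 0 and df.loc[-50, "code"] == 1

    def test_no_thresholds_no_change(self):
        t = _table([[55, 0, 0, 1], [-65, 0, 0, 0]])
        out = filter_disarticulated(t)
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_nonviable_rows_untouched(self):
        t = _table([[70, 0, 0, 0]])
        out = filter_disarticulated(t, z_positive_max=60)
        assert not out.df["disarticulated"].any()


class TestInclusion:
    def test_two_viable_poses_excluded(self):
        assert check_inclusion(_table([[0, 0, 0, 1], [5, 0, 0, 1], [10, 0, 0, 0]])) is False

    def test_four_viable_poses_included(self):
        assert check_inclusion(
            _table([[0, 0, 0, 1], [5, 0, 0, 1], [0, 5, 0, 1], [0, 0, 5, 1]])) is True

    def test_zero_viable_excluded(self):
        assert check_inclusion(_table([[0, 0, 0, 0]])) is False


class TestBuildJointModel:
    def test_aligned_fixture_pure_x_translation(self):
        model, _, _ = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=30.0, mesh_resolution=700, seed=5))
        # shift the distal mesh off along x; aligned frames must bring it back
        # with a pure translation along the JCS x axis
        distal = model.distal.copy()
        distal.apply_translation([7.5, 0.0, 0.0])
        jcs = Frame(model.cor, np.eye(3))
        mt = Frame(np.array([7.5, 0.0, 0.0]), np.eye(3))
        built = build_joint_model(
            model.proximal, distal, Sphere(model.cor, 9.5), model.gap_sphere,
            jcs, mt, Convention.PRIMATE_MARSUPIAL)
        assert np.allclose(built.reference.rotation, np.eye(3), atol=1e-9)
        assert abs(built.reference.translation[1]) < 1e-9
        assert abs(built.reference.translation[2]) < 1e-9
        assert np.isclose(built.reference.translation[0], -7.5, atol=1e-6)
        assert classify_pose(built, (0, 0, 0)) == 1

    def test_coincident_frames_identity(self):
        model, _, _ = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=30.0, mesh_resolution=700, seed=5))
        jcs = Frame(model.cor, np.eye(3))
        built = build_joint_model(
            model.proximal, model.distal, Sphere(model.cor, 9.5), model.gap_sphere,
            jcs, jcs, Convention.PRIMATE_MARSUPIAL)
        assert np.allclose(built.reference.matrix, np.eye(4), atol=1e-6)

    def test_gap_offset_recovered_along_x(self):
        # distal placed too deep relative to its frame: the builder must
        # slide it along JCS x until its surface touches the gap sphere
        model, _, _ = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=30.0, mesh_resolution=700, seed=5))
        distal = model.distal.copy()
        distal.apply_translation([9.0, 0.0, 0.0])
        jcs = Frame(model.cor, np.eye(3))
        mt = Frame(np.array([7.5, 0.0, 0.0]), np.eye(3))
        built = build_joint_model(
            model.proximal, distal, Sphere(model.cor, 9.5), model.gap_sphere,
            jcs, mt, Convention.PRIMATE_MARSUPIAL)
        assert np.isclose(built.reference.translation[0], -9.0, atol=0.2)
        assert classify_pose(built, (0, 0, 0)) == 1

    def test_colliding_reference_raises(self):
        model, _, _ = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=30.0, mesh_resolution=700, seed=5))
        fat = model.distal.copy()
        fat.apply_scale(1.2)  # head now larger than the socket
        jcs = Frame(model.cor, np.eye(3))
        with pytest.raises(ValueError):
            build_joint_model(model.proximal, fat, Sphere(model.cor, 9.5),
                              model.gap_sphere, jcs, jcs,
                              Convention.PRIMATE_MARSUPIAL)
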