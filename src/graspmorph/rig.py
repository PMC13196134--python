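"""Forward-kinematic joint rig and collision-based pose viability.

The joint model mirrors a two-bone articulation: a fixed proximal bone
(entocuneiform), a joint coordinate system (JCS) anchored at the centre of
rotation (COR, the centre of a sphere fitted between the articular
surfaces), and a mobile distal bone (first metatarsal) whose motion is a
pure rotation about the COR expressed in JCS axes with intrinsic z-y-x
ordering: z = flexion-extension (FE), y = abduction-adduction (ABAD),
x = inversion-eversion (IE). Positive z/y/x = flexion/adduction/eversion.

A pose is *viable* (code 1) when the bone meshes do not interpenetrate.
Poses that are collision-free but anatomically disarticulated (articular
surfaces no longer facing) are removed by configurable thresholds on the
z rotation, reproducing a visual-inspection step as configuration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import brentq

from graspmorph.collision import VoxelOccupancy, sweep_codes
from graspmorph.geometry import (
    Frame,
    RigidTransform,
    Sphere,
    meshes_interpenetrate,
    rotation_zyx,
    rotation_zyx_batch,
)

log = logging.getLogger(__name__)

__all__ = [
    "Convention",
    "JointModel",
    "PoseGrid",
    "PoseViabilityTable",
    "build_joint_model",
    "generate_pose_grid",
    "pose_transform",
    "classify_pose",
    "sweep",
    "filter_disarticulated",
    "check_inclusion",
]


class Convention(str, Enum):
    """Clade-specific axis conventions for the JCS and epiphyseal frames.

    In primates and marsupials the JCS y axis runs medio-laterally; in
    rodents and scandentians (tree shrews) it runs dorso-ventrally. Either
    way z maps to FE, y to ABAD and x to IE.
    """

    PRIMATE_MARSUPIAL = "primate_marsupial"
    RODENT_SCANDENTIAN = "rodent_scandentian"


@dataclass
class JointModel:
    """Two articulating bone meshes plus the kinematic scaffolding.

    ``reference`` carries the distal mesh from its file coordinates into the
    0/0/0 reference pose; every pose is then a rotation about ``cor`` in JCS
    axes applied on top of it. The reference pose must be viable.
    """

    proximal: trimesh.Trimesh
    distal: trimesh.Trimesh
    cor: np.ndarray
    jcs: Frame
    gap_sphere: Optional[Sphere]
    convention: Convention
    reference: RigidTransform

    def __post_init__(self):
        self.cor = np.asarray(self.cor, dtype=float)
        if not np.allclose(self.jcs.origin, self.cor, atol=1e-6):
            raise ValueError("JCS origin must coincide with the COR")

    def world_rotation(self, pose_zyx_deg) -> np.ndarray:
        """World rotation matrix for a pose: JCS-frame z-y-x rotation
        conjugated into world axes."""
        a = self.jcs.axes
        r = rotation_zyx(*pose_zyx_deg).rotation
        return a @ r @ a.T

    def world_rotation_batch(self, poses_zyx_deg: np.ndarray) -> np.ndarray:
        a = self.jcs.axes
        r = rotation_zyx_batch(poses_zyx_deg)
        return np.einsum("ij,pjk,lk->pil", a, r, a)

    def posed_distal_vertices(self, pose_zyx_deg) -> np.ndarray:
        t = pose_transform(self, pose_zyx_deg)
        return t.apply(self.distal.vertices)

    def posed_distal_mesh(self, pose_zyx_deg) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.posed_distal_vertices(pose_zyx_deg),
            faces=self.distal.faces, process=False,
        )


@dataclass(frozen=True)
class PoseGrid:
    """Regular pose grid centred on the reference pose, endpoints inclusive."""

    fe_range: float
    abad_range: float
    ie_range: float
    step: float
    poses: np.ndarray  # (n, 3) columns z, y, x in degrees

    def __len__(self):
        return len(self.poses)


@dataclass
class PoseViabilityTable:
    """Per-pose viability codes: the pipeline's central intermediate.

    Wraps a dataframe with columns ``z_deg, y_deg, x_deg, code,
    disarticulated``; code 1 means no mesh interpenetration at that pose.
    """

    df: pd.DataFrame

    COLUMNS = ("z_deg", "y_deg", "x_deg", "code", "disarticulated")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"viability table missing columns {sorted(missing)}")

    @property
    def viable(self) -> pd.DataFrame:
        """Viable, non-disarticulated rows."""
        return self.df[(self.df["code"] == 1) & (~self.df["disarticulated"])]

    @property
    def n_viable(self) -> int:
        return int(len(self.viable))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PoseViabilityTable":
        df = pd.read_csv(path)
        df["disarticulated"] = df["disarticulated"].astype(bool)
        return cls(df)


# ---------------------------------------------------------------------------


def generate_pose_grid(fe_range: float = 270.0, abad_range: float = 180.0,
                       ie_range: float = 180.0, step: float = 5.0) -> PoseGrid:
    """Pose grid with z in ±fe_range/2, y in ±abad_range/2, x in ±ie_range/2.

    Endpoints inclusive and the grid centred on the reference pose, so the
    defaults give (270/5+1)·(180/5+1)² = 75,295 candidate poses including
    (0, 0, 0).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    for name, rng in (("fe", fe_range), ("abad", abad_range), ("ie", ie_range)):
        if rng < 0 or abs(round(rng / step) * step - rng) > 1e-9:
            raise ValueError(f"{name} range {rng} is not divisible by step {step}")

    def axis(rng):
        n = int(round(rng / step))
        return (np.arange(n + 1) - n / 2.0) * step

    zs, ys, xs = axis(fe_range), axis(abad_range), axis(ie_range)
    poses = np.array(list(product(zs, ys, xs)), dtype=float)
    return PoseGrid(fe_range, abad_range, ie_range, step, poses)


def pose_transform(model: JointModel, pose_zyx_deg) -> RigidTransform:
    """Rigid transform carrying the distal mesh (file coordinates) to a pose:
    the reference transform followed by a pure rotation about the COR in JCS
    axes. Distances to the COR are preserved relative to the reference pose."""
    w = model.world_rotation(pose_zyx_deg)
    rot_about_cor = RigidTransform(w, model.cor - w @ model.cor)
    return rot_about_cor.compose(model.reference)


def classify_pose(model: JointModel, pose_zyx_deg) -> int:
    """Exact viability code for one pose: 1 iff the posed distal mesh does
    not interpenetrate the proximal mesh."""
    posed = model.posed_distal_mesh(pose_zyx_deg)
    return 0 if meshes_interpenetrate(model.proximal, posed, names=("proximal", "distal")) else 1


def _sample_points(mesh: trimesh.Trimesh) -> np.ndarray:
    """Collision sample points: vertices plus face centroids, shuffled
    deterministically so early-exit scans hit colliding regions quickly."""
    pts = np.vstack([mesh.vertices, mesh.triangles_center])
    rng = np.random.default_rng(0)
    return pts[rng.permutation(len(pts))]


def sweep(model: JointModel, grid: PoseGrid, engine: str = "voxel",
          resolution: int = 96) -> PoseViabilityTable:
    """Classify every grid pose as viable (1) or colliding (0).

    ``engine="voxel"`` (default) uses the conservative voxel-occupancy
    predicate of :mod:`graspmorph.collision`, suitable for 75k-pose grids;
    ``engine="exact"`` runs the full triangle-intersection predicate per
    pose and is intended for small grids and verification.
    """
    poses = grid.poses
    if engine == "exact":
        codes = np.empty(len(poses), dtype=np.uint8)
        for i, p in enumerate(poses):
            codes[i] = classify_pose(model, p)
            if (i + 1) % 500 == 0:
                log.info("exact sweep: %d/%d poses", i + 1, len(poses))
    elif engine == "voxel":
        ref_distal = trimesh.Trimesh(
            vertices=model.reference.apply(model.distal.vertices),
            faces=model.distal.faces, process=False,
        )
        grid_p = VoxelOccupancy(model.proximal, resolution)
        grid_d = VoxelOccupancy(ref_distal, resolution)
        pts_d = _sample_points(ref_distal) - model.cor
        pts_p = _sample_points(model.proximal) - model.cor
        rots = model.world_rotation_batch(poses)
        codes = sweep_codes(rots, model.cor, pts_d, grid_p, pts_p, grid_d)
        log.info("voxel sweep: %d poses, %d viable", len(poses), int(codes.sum()))
    else:
        raise ValueError(f"unknown sweep engine '{engine}'")

    df = pd.DataFrame({
        "z_deg": poses[:, 0], "y_deg": poses[:, 1], "x_deg": poses[:, 2],
        "code": codes.astype(int),
        "disarticulated": np.zeros(len(poses), dtype=bool),
    })
    return PoseViabilityTable(df)


def filter_disarticulated(table: PoseViabilityTable,
                          z_positive_max: Optional[float] = None,
                          z_negative_min: Optional[float] = None) -> PoseViabilityTable:
    """Recode viable poses beyond the articulation thresholds.

    Viable rows with ``z > z_positive_max`` or ``z < z_negative_min`` are
    flagged disarticulated and recoded 0; other rows are untouched. Either
    threshold may be None (no cut on that side).
    """
    df = table.df.copy()
    mask = np.zeros(len(df), dtype=bool)
    if z_positive_max is not None:
        mask |= (df["code"] == 1) & (df["z_deg"] > z_positive_max)
    if z_negative_min is not None:
        mask |= (df["code"] == 1) & (df["z_deg"] < z_negative_min)
    df.loc[mask, "disarticulated"] = True
    df.loc[mask, "code"] = 0
    if mask.any():
        log.info("disarticulation filter removed %d viable poses", int(mask.sum()))
    return PoseViabilityTable(df)


def check_inclusion(table: PoseViabilityTable, min_viable: int = 4) -> bool:
    """Specimen inclusion gate for pose-space analysis.

    A 3D alpha shape needs at least four affinely independent points, so
    specimens with fewer viable poses are excluded (as happens for joints
    with only two viable poses).
    """
    n = table.n_viable
    if n < min_viable:
        log.info("specimen excluded: %d viable poses (< %d)", n, min_viable)
        return False
    return True


# ---------------------------------------------------------------------------


def build_joint_model(proximal: trimesh.Trimesh, distal: trimesh.Trimesh,
                      cor_sphere: Sphere, gap_sphere: Sphere,
                      articular_surface_frame: Frame,
                      metatarsal_proximal_frame: Frame,
                      convention: Convention,
                      validate: bool = True) -> JointModel:
    """Assemble the forward-kinematic joint model.

    The JCS is placed at the COR-sphere centre with the articular-surface
    frame's axes (x perpendicular to the articular surface in either
    convention). The reference transform rotates the distal bone so its
    proximal frame axes are parallel and co-directed with the JCS axes, then
    slides it along the JCS x axis until its surface touches the
    interarticular gap sphere, preserving the spacing that sphere defines.
    Raises if the resulting reference pose interpenetrates.
    """
    jcs = Frame(cor_sphere.center, articular_surface_frame.axes)
    rot = jcs.axes @ metatarsal_proximal_frame.axes.T
    o_mt = metatarsal_proximal_frame.origin

    def placed(s):
        return RigidTransform(
            rot, jcs.origin + s * jcs.axis_x - rot @ o_mt
        )

    import trimesh.triangles as tt

    verts = distal.vertices
    faces = distal.faces
    gc, gr = gap_sphere.center, gap_sphere.radius

    from graspmorph.geometry import points_in_mesh

    def clearance(s):
        v = placed(s).apply(verts)
        tris = v[faces]
        closest = tt.closest_point(tris, np.broadcast_to(gc, (len(tris), 3)).copy())
        dist = float(np.linalg.norm(closest - gc, axis=1).min())
        posed = trimesh.Trimesh(vertices=v, faces=faces, process=False)
        if points_in_mesh(posed, gc[None, :])[0]:
            dist = -dist  # sphere centre swallowed by the bone
        return dist - gr

    # find the x-offset at which the distal surface touches the gap sphere;
    # misfits below the mesh facet scale count as already satisfied
    span = float(np.linalg.norm(distal.extents)) + 2 * gr
    edges = np.linalg.norm(
        verts[distal.edges_unique[:, 0]] - verts[distal.edges_unique[:, 1]], axis=1)
    gap_tol = max(1e-3 * span, 0.25 * float(np.median(edges)))
    c0 = clearance(0.0)
    if abs(c0) <= gap_tol:
        s_star = 0.0
    else:
        h = 1e-3 * span
        slope = (clearance(h) - clearance(-h)) / (2 * h)
        if abs(slope) < 1e-12:
            raise ValueError("gap clearance insensitive to the JCS x offset")
        direction = -np.sign(c0) * np.sign(slope)
        s1, c1 = 0.0, c0
        for _ in range(64):
            s1 += direction * span / 16.0
            c1 = clearance(s1)
            if c0 * c1 <= 0:
                break
        else:
            raise ValueError("could not bracket the gap-preserving offset along JCS x")
        s_star = brentq(clearance, min(0.0, s1), max(0.0, s1), xtol=1e-10)

    reference = placed(s_star)
    model = JointModel(proximal, distal, cor_sphere.center, jcs, gap_sphere,
                       Convention(convention), reference)
    if validate and classify_pose(model, (0.0, 0.0, 0.0)) != 1:
        raise ValueError("reference pose interpenetrates; all reference poses must be viable")
    return model
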