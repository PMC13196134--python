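"""Synthetic joints, muscle fixtures and metadata with known ground truth.

Scan-derived bone meshes are not redistributable, so every pipeline stage
is exercised on constructed geometry whose correct answer is known in
closed form:

* a ball-and-socket joint (spherical head + cylindrical shaft inside a
  conical-opening cup) whose viable poses satisfy an analytic clearance
  predicate on the shaft swing angle;
* an anisotropic socket emulating the saddle joint's independent
  flexion-extension and abduction-adduction clearances (the cup is scaled
  anisotropically, giving an elliptic-cone opening);
* a box-in-tunnel fixture engineered to admit exactly two viable poses,
  mirroring joints excluded from pose-space analysis;
* muscle attachment fixtures with analytic moment arms;
* twisted synthetic metatarsals with a prescribed torsion angle;
* a specimen metadata table emulating a museum-collection study sample.

All randomness flows through a single seeded generator per fixture;
meshes regenerate bit-identically for a given spec.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import trimesh

from graspmorph.geometry import Cylinder, Frame, RigidTransform, Sphere
from graspmorph.momentarms import MusclePath
from graspmorph.rig import Convention, JointModel, classify_pose
from graspmorph.torsion import ArticularPatch

__all__ = [
    "BallSocketSpec",
    "SaddleSpec",
    "make_ball_and_socket",
    "make_saddle_joint",
    "make_two_pose_fixture",
    "make_muscle_fixture",
    "make_twisted_metatarsal",
    "make_specimen_table",
    "revolve_profile",
]


# ---------------------------------------------------------------------------
# surface-of-revolution meshing


def revolve_profile(profile: np.ndarray, n_theta: int, phase: float = 0.0) -> trimesh.Trimesh:
    """Triangulate the surface of revolution of a profile polyline about the
    x axis.

    ``profile`` is an (m, 2) array of (x, r) samples with r = 0 at both ends
    (both endpoints on the axis), which closes the surface into a watertight
    shell. ``phase`` offsets the azimuthal tessellation.
    """
    prof = np.asarray(profile, dtype=float)
    if prof.ndim != 2 or prof.shape[1] != 2 or len(prof) < 3:
        raise ValueError("profile must be an (m, 2) array with m >= 3")
    if abs(prof[0, 1]) > 1e-12 or abs(prof[-1, 1]) > 1e-12:
        raise ValueError("profile must start and end on the axis (r = 0)")
    if np.any(prof[1:-1, 1] <= 0):
        raise ValueError("interior profile points must have r > 0")

    theta = phase + np.arange(n_theta) * (2 * np.pi / n_theta)
    ct, st = np.cos(theta), np.sin(theta)

    verts = [np.array([[prof[0, 0], 0.0, 0.0]])]
    for x, r in prof[1:-1]:
        verts.append(np.column_stack([np.full(n_theta, x), r * ct, r * st]))
    verts.append(np.array([[prof[-1, 0], 0.0, 0.0]]))
    vertices = np.vstack(verts)

    m = len(prof) - 2  # number of rings
    ring0 = 1

    def ring(i):
        return ring0 + i * n_theta

    faces = []
    # start pole fan
    for j in range(n_theta):
        faces.append([0, ring(0) + j, ring(0) + (j + 1) % n_theta])
    # quad strips between rings
    for i in range(m - 1):
        a, b = ring(i), ring(i + 1)
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    # end pole fan
    last = ring(m - 1)
    apex = ring(m)
    for j in range(n_theta):
        faces.append([last + j, apex, last + (j + 1) % n_theta])

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("revolution mesh failed watertightness check")
    return mesh


def _arc(radius, theta0, theta1, n):
    t = np.linspace(theta0, theta1, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


def _cup_mesh(socket_radius: float, thickness: float, opening_half_angle_deg: float,
              n_theta: int, n_arc: int, phase: float = 0.0) -> trimesh.Trimesh:
    """Watertight cup: spherical socket of the given inner radius with a
    conical opening (half-angle from the +x axis), closed outer shell."""
    phi = np.radians(opening_half_angle_deg)
    r_in = socket_radius
    r_out = socket_radius + thickness
    outer = _arc(r_out, np.pi, phi, n_arc)
    inner = _arc(r_in, phi, np.pi, n_arc)
    profile = np.vstack([outer, inner])
    profile[0, 1] = 0.0
    profile[-1, 1] = 0.0
    return revolve_profile(profile, n_theta, phase)


def _lollipop_mesh(head_radius: float, shaft_radius: float, shaft_length: float,
                   n_theta: int, n_arc: int, phase: float = 0.0) -> trimesh.Trimesh:
    """Watertight distal bone: spherical head centred at the origin with a
    cylindrical shaft along +x ending in a flat cap at x = shaft_length."""
    if not shaft_radius < head_radius:
        raise ValueError("shaft radius must be smaller than head radius")
    theta_j = np.arcsin(shaft_radius / head_radius)
    head = _arc(head_radius, np.pi, theta_j, n_arc)  # ends at (x_j, shaft_radius)
    profile = np.vstack([head, [[shaft_length, shaft_radius]], [[shaft_length, 0.0]]])
    profile[0, 1] = 0.0
    return revolve_profile(profile, n_theta, phase)


def _resolution_params(target_faces: int):
    n_theta = max(16, int(round(np.sqrt(target_faces / 2.0))))
    n_arc = max(8, int(round(target_faces / (2.0 * n_theta))))
    return n_theta, n_arc


def _world_jcs(origin=(0.0, 0.0, 0.0)) -> Frame:
    return Frame(np.asarray(origin, float), np.eye(3))


# ---------------------------------------------------------------------------
# ball-and-socket oracle fixture


@dataclass(frozen=True)
class BallSocketSpec:
    """Parameters of the ball-and-socket oracle joint.

    The cup's socket radius equals ``head_radius``; the head sphere is
    shrunk by ``gap`` to leave an even interarticular space. The shaft
    leaves the cup through a conical opening of ``opening_half_angle``
    (degrees from the +x axis).
    """

    opening_half_angle: float = 30.0
    head_radius: float = 10.0
    gap: float = 0.5
    shaft_radius: float = 1.5
    shaft_length: float = 25.0
    mesh_resolution: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (5.0 <= self.opening_half_angle <= 90.0):
            raise ValueError("opening half-angle must be in [5, 90] degrees")
        if not self.shaft_radius < self.head_radius:
            raise ValueError("shaft radius must be smaller than head radius")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")


def make_ball_and_socket(spec: BallSocketSpec):
    """Build the ball-and-socket joint and its analytic viability predicate.

    The shaft axis at a pose points along the rotated +x axis; with the cup
    rim sitting at distance ``head_radius`` from the centre of rotation, the
    shaft clears the rim iff its swing angle psi (angle of the rotated +x
    axis from the opening axis, cos psi = cos z cos y) satisfies

        psi <= opening_half_angle - asin(shaft_radius / head_radius).

    Returns ``(model, predicate, params)`` where ``predicate(pose)`` maps an
    (z, y, x) degree triple to the analytic viability boolean.
    """
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0, 2 * np.pi))
    n_theta, n_arc = _resolution_params(spec.mesh_resolution)
    thickness = 0.25 * spec.head_radius

    cup = _cup_mesh(spec.head_radius, thickness, spec.opening_half_angle,
                    n_theta, n_arc, phase)
    head = _lollipop_mesh(spec.head_radius - spec.gap, spec.shaft_radius,
                          spec.shaft_length, n_theta, n_arc,
                          phase + np.pi / n_theta)
    # tiny seeded radial jitter: varies tessellation detail across seeds
    # without moving the analytic boundary measurably
    for mesh in (cup, head):
        v = mesh.vertices.copy()
        v += rng.normal(scale=1e-3 * spec.head_radius, size=v.shape)
        mesh.vertices = v

    # interarticular sphere sandwiched between head and socket on the -x
    # side (the +x axis is occupied by the shaft)
    gap_sphere = Sphere(
        center=np.array([-(spec.head_radius - spec.gap / 2.0), 0.0, 0.0]),
        radius=max(spec.gap / 2.0, 1e-6),
    )
    model = JointModel(
        proximal=cup, distal=head, cor=np.zeros(3), jcs=_world_jcs(),
        gap_sphere=gap_sphere, convention=Convention.PRIMATE_MARSUPIAL,
        reference=RigidTransform.identity(),
    )
    if classify_pose(model, (0.0, 0.0, 0.0)) != 1:
        raise ValueError("ball-and-socket spec makes the reference pose collide")

    margin = np.degrees(np.arcsin(spec.shaft_radius / spec.head_radius))
    limit = spec.opening_half_angle - margin

    def predicate(pose) -> bool:
        z, y = float(pose[0]), float(pose[1])
        cos_psi = np.cos(np.radians(z)) * np.cos(np.radians(y))
        psi = np.degrees(np.arccos(np.clip(cos_psi, -1.0, 1.0)))
        return bool(psi <= limit)

    params = {"swing_limit_deg": float(limit),
              "opening_half_angle_deg": spec.opening_half_angle,
              "shaft_margin_deg": float(margin)}
    return model, predicate, params


def swing_angle_deg(poses: np.ndarray) -> np.ndarray:
    """Swing angle of the rotated +x axis for (n, 3) z-y-x degree poses."""
    p = np.radians(np.atleast_2d(np.asarray(poses, float)))
    cos_psi = np.cos(p[:, 0]) * np.cos(p[:, 1])
    return np.degrees(np.arccos(np.clip(cos_psi, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# anisotropic ("saddle-like") fixture


@dataclass(frozen=True)
class SaddleSpec:
    """Anisotropic joint with independent FE and ABAD angular clearances.

    ``congruence_depth`` sets the radial interarticular spacing between
    head and socket (mm). Clearances are in degrees and must be in
    [10, 70].
    """

    fe_clearance: float = 40.0
    abad_clearance: float = 20.0
    congruence_depth: float = 0.5
    mesh_resolution: int = 5000
    seed: int = 0

    def __post_init__(self):
        for name, c in (("fe", self.fe_clearance), ("abad", self.abad_clearance)):
            if not (10.0 <= c <= 70.0):
                raise ValueError(f"{name} clearance must be in [10, 70] degrees")
        if not self.congruence_depth > 0:
            raise ValueError("congruence depth must be positive")


_SADDLE_R = 10.0
_SADDLE_PHI0 = 40.0
_SADDLE_RS = 1.5


def make_saddle_joint(spec: SaddleSpec) -> JointModel:
    """Joint with independent angular clearance about z (FE) and y (ABAD).

    A conical-opening cup is scaled anisotropically: FE (rotation about z)
    swings the shaft in the +-y direction, so the cup's y extent is scaled
    by tan(fe_clearance + shaft margin)/tan(base opening); likewise the z
    extent from the ABAD clearance. Larger clearance strictly enlarges the
    cup, so the viable pose set grows monotonically with either parameter.
    """
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0, 2 * np.pi))
    n_theta, n_arc = _resolution_params(spec.mesh_resolution)

    margin = np.degrees(np.arcsin(_SADDLE_RS / _SADDLE_R))
    k_y = np.tan(np.radians(spec.fe_clearance + margin)) / np.tan(np.radians(_SADDLE_PHI0))
    k_z = np.tan(np.radians(spec.abad_clearance + margin)) / np.tan(np.radians(_SADDLE_PHI0))

    cup = _cup_mesh(_SADDLE_R, 0.25 * _SADDLE_R, _SADDLE_PHI0, n_theta, n_arc, phase)
    v = cup.vertices.copy()
    v[:, 1] *= k_y
    v[:, 2] *= k_z
    cup.vertices = v

    head_radius = max(2.0 * _SADDLE_RS, 0.5 * _SADDLE_R * min(1.0, k_y, k_z))
    head = _lollipop_mesh(head_radius, _SADDLE_RS, 2.5 * _SADDLE_R,
                          n_theta, n_arc, phase + np.pi / n_theta)

    gap_sphere = Sphere(
        center=np.array([-(head_radius + _SADDLE_R) / 2.0, 0.0, 0.0]),
        radius=max((_SADDLE_R - head_radius) / 2.0, spec.congruence_depth / 2.0),
    )
    model = JointModel(
        proximal=cup, distal=head, cor=np.zeros(3), jcs=_world_jcs(),
        gap_sphere=gap_sphere, convention=Convention.PRIMATE_MARSUPIAL,
        reference=RigidTransform.identity(),
    )
    if classify_pose(model, (0.0, 0.0, 0.0)) != 1:
        raise ValueError("saddle spec makes the reference pose collide")
    return model


# ---------------------------------------------------------------------------
# exactly-two-viable-poses fixture


def _hollow_box_with_tunnel(outer_lo, outer_hi, cavity_lo, cavity_hi,
                            tunnel_half_y, tunnel_half_z) -> trimesh.Trimesh:
    """Watertight hollow box whose +x wall carries a rectangular tunnel
    from the cavity to the outside (a genus-1 shell)."""
    ox0, oy0, oz0 = outer_lo
    ox1, oy1, oz1 = outer_hi
    cx0, cy0, cz0 = cavity_lo
    cx1, cy1, cz1 = cavity_hi
    ty, tz = tunnel_half_y, tunnel_half_z

    def rect_corners(x, hy, hz):
        return [(x, -hy, -hz), (x, hy, -hz), (x, hy, hz), (x, -hy, hz)]

    verts = []

    def add(p):
        verts.append(p)
        return len(verts) - 1

    # outer box corners
    o = [add((x, y, z)) for x in (ox0, ox1) for y in (oy0, oy1) for z in (oz0, oz1)]
    # cavity corners
    c = [add((x, y, z)) for x in (cx0, cx1) for y in (cy0, cy1) for z in (cz0, cz1)]
    # tunnel rims on the outer +x face and the cavity +x face
    rim_out = [add(p) for p in rect_corners(ox1, ty, tz)]
    rim_in = [add(p) for p in rect_corners(cx1, ty, tz)]
    # outer +x face corners and cavity +x face corners as rings
    face_out = [add(p) for p in [(ox1, oy0, oz0), (ox1, oy1, oz0), (ox1, oy1, oz1), (ox1, oy0, oz1)]]
    face_cav = [add(p) for p in [(cx1, cy0, cz0), (cx1, cy1, cz0), (cx1, cy1, cz1), (cx1, cy0, cz1)]]

    faces = []

    def quad(a, b, cc, d):
        faces.append([a, b, cc])
        faces.append([a, cc, d])

    def ring(outer_ring, inner_ring):
        for k in range(4):
            kn = (k + 1) % 4
            quad(outer_ring[k], outer_ring[kn], inner_ring[kn], inner_ring[k])

    # outer box: five solid faces (indices into o: x y z bit order x*4+y*2+z)
    O = lambda x, y, z: o[x * 4 + y * 2 + z]
    quad(O(0, 0, 0), O(0, 0, 1), O(0, 1, 1), O(0, 1, 0))  # -x
    quad(O(0, 0, 0), O(1, 0, 0), O(1, 0, 1), O(0, 0, 1))  # -y
    quad(O(0, 1, 0), O(0, 1, 1), O(1, 1, 1), O(1, 1, 0))  # +y
    quad(O(0, 0, 0), O(0, 1, 0), O(1, 1, 0), O(1, 0, 0))  # -z
    quad(O(0, 0, 1), O(1, 0, 1), O(1, 1, 1), O(0, 1, 1))  # +z
    ring(face_out, rim_out)  # +x face with tunnel hole

    # cavity: five solid faces (normals toward the cavity interior)
    C = lambda x, y, z: c[x * 4 + y * 2 + z]
    quad(C(0, 0, 0), C(0, 1, 0), C(0, 1, 1), C(0, 0, 1))  # cavity -x
    quad(C(0, 0, 0), C(0, 0, 1), C(1, 0, 1), C(1, 0, 0))  # cavity -y
    quad(C(0, 1, 0), C(1, 1, 0), C(1, 1, 1), C(0, 1, 1))  # cavity +y
    quad(C(0, 0, 0), C(1, 0, 0), C(1, 1, 0), C(0, 1, 0))  # cavity -z
    quad(C(0, 0, 1), C(0, 1, 1), C(1, 1, 1), C(1, 0, 1))  # cavity +z
    ring(rim_in, face_cav)  # cavity +x face with tunnel hole

    # tunnel walls between the two rims
    ring(rim_out, rim_in)

    mesh = trimesh.Trimesh(vertices=np.array(verts, float), faces=np.array(faces), process=True)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("hollow box construction failed watertightness check")
    return mesh


def make_two_pose_fixture():
    """A joint engineered to admit exactly two viable poses on a 5° grid.

    A rectangular-section distal bar passes through a matching rectangular
    tunnel in a hollow proximal block. The bar is pre-rotated 2.5° about
    the x axis, which shifts the inversion-eversion contact window so that
    only x = 0° and x = -5° (at z = y = 0) clear the tunnel; every swing of
    5° or more collides at the tunnel, and large swings collide with the
    cavity walls. Mirrors specimens excluded from pose-space analysis for
    exhibiting only two viable poses.
    """
    proximal = _hollow_box_with_tunnel(
        outer_lo=(-16.0, -14.0, -14.0), outer_hi=(12.0, 14.0, 14.0),
        cavity_lo=(-12.0, -10.0, -10.0), cavity_hi=(8.0, 10.0, 10.0),
        tunnel_half_y=6.6, tunnel_half_z=4.6,
    )
    bar = trimesh.creation.box(extents=(23.0, 12.0, 8.0))
    bar.apply_translation((13.5, 0.0, 0.0))  # spans x in [2, 25]
    delta = np.radians(2.5)
    rot = trimesh.transformations.rotation_matrix(delta, (1.0, 0.0, 0.0))
    bar.apply_transform(rot)

    gap_sphere = Sphere(center=np.array([10.0, 0.0, 6.0]), radius=0.3)
    model = JointModel(
        proximal=proximal, distal=bar, cor=np.zeros(3), jcs=_world_jcs(),
        gap_sphere=gap_sphere, convention=Convention.RODENT_SCANDENTIAN,
        reference=RigidTransform.identity(),
    )
    if classify_pose(model, (0.0, 0.0, 0.0)) != 1:
        raise RuntimeError("two-pose fixture reference pose collides")
    return model


# ---------------------------------------------------------------------------
# muscle fixtures with analytic moment arms


def make_muscle_fixture(kind: str, params: Optional[dict] = None):
    """Muscle attachment fixture with a closed-form moment arm.

    Kinds (all assume a model with the COR at the origin and a world-axis
    JCS, e.g. the ball-and-socket fixture):

    * ``through_cor`` — insertion at the COR: the line of action contains
      the COR at every pose, so the moment arm is identically 0.
    * ``perpendicular_at_d`` — line parallel to the x axis at distance
      ``d``: moment arm at the reference pose is exactly ``d``.
    * ``planar_cosine`` — insertion on a circle of radius ``r`` in the
      z-rotation plane, origin far away in the same plane: the moment arm
      follows r·|sin(z - z0)| with z0 = origin angle - insertion angle,
      so the maximum sits at z = z0 ± 90°.

    Returns ``(muscle, analytic_imma, params)`` where ``analytic_imma``
    maps a (z, y, x) pose to the closed-form moment arm (model units).
    """
    p = dict(params or {})
    if kind == "through_cor":
        origin = np.asarray(p.get("origin", (20.0, 5.0, 0.0)), float)
        muscle = MusclePath("through_cor", origin, np.zeros(3), p.get("muscle_length", 30.0))

        def analytic(pose):
            return 0.0

        return muscle, analytic, {}

    if kind == "perpendicular_at_d":
        d = float(p.get("d", 7.0))
        origin = np.array([-50.0, d, 0.0])
        insertion = np.array([5.0, d, 0.0])
        muscle = MusclePath("perpendicular_at_d", origin, insertion, p.get("muscle_length", 30.0))

        def analytic(pose):
            if np.allclose(pose, 0.0):
                return d
            raise ValueError("analytic value defined at the reference pose only")

        return muscle, analytic, {"d": d}

    if kind == "planar_cosine":
        r = float(p.get("r", 8.0))
        big_d = float(p.get("D", 2000.0))
        theta_i = float(p.get("insertion_angle_deg", 10.0))
        theta_o = float(p.get("origin_angle_deg", 55.0))
        insertion = r * np.array([np.cos(np.radians(theta_i)), np.sin(np.radians(theta_i)), 0.0])
        origin = big_d * np.array([np.cos(np.radians(theta_o)), np.sin(np.radians(theta_o)), 0.0])
        z0 = theta_o - theta_i
        muscle = MusclePath("planar_cosine", origin, insertion, p.get("muscle_length", 30.0))

        def analytic(pose):
            z = float(pose[0])
            return r * abs(np.sin(np.radians(z - z0)))

        return muscle, analytic, {"r": r, "z0_deg": z0, "argmax_z_deg": z0 + 90.0}

    raise ValueError(f"unknown muscle fixture kind '{kind}'")


# ---------------------------------------------------------------------------
# twisted synthetic metatarsal (torsion ground truth)


def make_twisted_metatarsal(alpha_deg: float, convention: Convention,
                            seed: int = 0, noise: float = 0.01):
    """Synthetic metatarsal epiphyses with a prescribed torsion angle.

    Emits a proximal and distal articular patch, each a partial cylinder
    surface, whose cylinder axes are chosen so that the clade-convention
    frame construction recovers exactly ``alpha_deg`` of rotation about the
    long (x) axis. Arcs face the +x direction on both ends so the patch
    centroids stay on the long axis. Gaussian vertex jitter of ``noise`` mm
    (seeded) emulates segmentation roughness.

    Returns ``(proximal_patch, distal_patch, head_axis, proximal_axis)``
    with the true cylinder axes for seeding the fits.
    """
    convention = Convention(convention)
    rng = np.random.default_rng(seed)
    alpha = np.radians(alpha_deg)
    rot_x = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(alpha), -np.sin(alpha)],
        [0.0, np.sin(alpha), np.cos(alpha)],
    ])
    if convention is Convention.PRIMATE_MARSUPIAL:
        prox_axis = np.array([0.0, 0.0, 1.0])  # proximal z follows this
        dist_axis0 = np.array([0.0, 1.0, 0.0])  # distal y follows this
    else:
        prox_axis = np.array([0.0, 1.0, 0.0])  # proximal y
        dist_axis0 = np.array([0.0, 0.0, 1.0])  # distal z
    dist_axis = rot_x @ dist_axis0

    length = 10.0

    def patch(center, axis):
        # partial cylinder surface, radius 1.5, arc 140° centred on +x
        radius, half_arc, axial = 1.5, np.radians(70.0), 3.0
        e1 = np.array([1.0, 0.0, 0.0])  # +x is orthogonal to every axis used here
        e2 = np.cross(axis, e1)
        u = np.linspace(-half_arc, half_arc, 24)
        v = np.linspace(-axial / 2, axial / 2, 10)
        uu, vv = np.meshgrid(u, v)
        pts = (center[None, :]
               + radius * np.cos(uu).ravel()[:, None] * e1[None, :]
               + radius * np.sin(uu).ravel()[:, None] * e2[None, :]
               + vv.ravel()[:, None] * axis[None, :])
        pts = pts + rng.normal(scale=noise, size=pts.shape)
        # grid triangulation
        nu, nv = len(u), len(v)
        faces = []
        for i in range(nv - 1):
            for j in range(nu - 1):
                a = i * nu + j
                faces.append([a, a + 1, a + nu])
                faces.append([a + 1, a + nu + 1, a + nu])
        mesh = trimesh.Trimesh(vertices=pts, faces=np.array(faces), process=False)
        return ArticularPatch(mesh)

    proximal_patch = patch(np.zeros(3), prox_axis)
    distal_patch = patch(np.array([length, 0.0, 0.0]), dist_axis)
    return proximal_patch, distal_patch, dist_axis, prox_axis


# ---------------------------------------------------------------------------
# specimen metadata


_CLADES = (
    ("strepsirrhine", Convention.PRIMATE_MARSUPIAL),
    ("platyrrhine", Convention.PRIMATE_MARSUPIAL),
    ("scandentian", Convention.RODENT_SCANDENTIAN),
    ("rodent", Convention.RODENT_SCANDENTIAN),
    ("marsupial", Convention.PRIMATE_MARSUPIAL),
)

_PRESERVATION_CHOICES = (
    frozenset(),
    frozenset({"ethanol_short"}),
    frozenset({"ethanol_long"}),
    frozenset({"ethanol_short", "formalin_month"}),
)


def make_specimen_table(n_specimens: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic specimen metadata emulating a museum study sample.

    Body masses are drawn log-uniformly from 6–300 g (the span of small
    arboreal grasping mammals studied with diceCT), preservation flags
    cover the fluid-storage categories, and each specimen carries a clade
    and the matching axis-convention tag. Deterministic per seed.
    """
    if n_specimens < 1:
        raise ValueError("need at least one specimen")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_specimens):
        clade, convention = _CLADES[rng.integers(len(_CLADES))]
        mass = float(np.exp(rng.uniform(np.log(6.0), np.log(300.0))))
        pres = _PRESERVATION_CHOICES[rng.integers(len(_PRESERVATION_CHOICES))]
        rows.append({
            "specimen": f"SYN_{clade[:3].upper()}{i:02d}",
            "clade": clade,
            "convention": convention.value,
            "body_mass_g": round(mass, 2),
            "ethanol_short": "ethanol_short" in pres,
            "ethanol_long": "ethanol_long" in pres,
            "formalin_month": "formalin_month" in pres,
        })
    return pd.DataFrame(rows)
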