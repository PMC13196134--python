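"""Geometric primitives shared by every pipeline stage.

Rotation algebra (intrinsic z-y-x Tait-Bryan), algebraic sphere and
axis-seeded cylinder fitting, point-to-infinite-line distance, and the
watertight-mesh interpenetration predicate that drives the osteological
range-of-motion sweep.

Units: lengths are millimetres unless a function is explicitly operating
in pose space (degrees).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "Sphere",
    "Cylinder",
    "Frame",
    "RigidTransform",
    "rotation_zyx",
    "rotation_zyx_batch",
    "fit_sphere",
    "fit_cylinder",
    "point_line_distance",
    "meshes_interpenetrate",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Sphere:
    """A sphere, used for the centre of rotation and the interarticular gap."""

    center: np.ndarray
    radius: float
    residual_rms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("sphere centre must be a finite 3-vector")
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class Cylinder:
    """An infinite cylinder defined by a point on its axis, the axis direction
    (unit vector) and a radius. Used for the torsion-measurement fits on the
    metatarsal head and the distal articular concavity."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    residual_rms: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or not np.all(np.isfinite(d)):
            raise ValueError("cylinder axis direction must be a nonzero finite vector")
        object.__setattr__(self, "axis_point", p)
        object.__setattr__(self, "axis_direction", d / n)
        if not self.radius > 0:
            raise ValueError("cylinder radius must be positive")


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal coordinate frame (origin + axes).

    ``axes`` holds the unit axis vectors as columns ``[x | y | z]``, so a
    point with local coordinates ``q`` sits at ``origin + axes @ q`` in
    world coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        a = np.asarray(self.axes, dtype=float)
        if o.shape != (3,) or a.shape != (3, 3):
            raise ValueError("frame needs a 3-vector origin and 3x3 axes matrix")
        if not np.allclose(a.T @ a, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        x, y, z = a[:, 0], a[:, 1], a[:, 2]
        if np.linalg.norm(np.cross(x, y) - z) > 1e-8:
            raise ValueError("frame must be right-handed (x cross y = z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", a)

    @property
    def axis_x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def axis_y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def axis_z(self) -> np.ndarray:
        return self.axes[:, 2]

    @staticmethod
    def from_axes(origin, x, y) -> "Frame":
        """Build a frame from an origin, an x axis and an approximate y axis
        (re-orthogonalised; z completes the right-handed triad)."""
        x = np.asarray(x, float)
        x = x / np.linalg.norm(x)
        y = np.asarray(y, float)
        y = y - x * (x @ y)
        ny = np.linalg.norm(y)
        if ny < 1e-12:
            raise ValueError("y axis parallel to x axis")
        y = y / ny
        z = np.cross(x, y)
        return Frame(np.asarray(origin, float), np.column_stack([x, y, z]))


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rigid transform needs a 3x3 rotation and 3-vector translation")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_translation(t) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


# ---------------------------------------------------------------------------
# rotations


def rotation_zyx(z_deg: float, y_deg: float, x_deg: float) -> RigidTransform:
    """Intrinsic z-y-x Tait-Bryan rotation, ``Rz(z) @ Ry(y) @ Rx(x)``.

    This is the hierarchy of the forward-kinematic joint rig: rotating about
    z carries the y and x axes (and the bone) with it, rotating about y
    carries the x axis, and x rotates only the bone. Angles in degrees.
    """
    if not np.all(np.isfinite([z_deg, y_deg, x_deg])):
        raise ValueError("angles must be finite")
    return RigidTransform(_rzyx_matrix(z_deg, y_deg, x_deg), np.zeros(3))


def _rzyx_matrix(z_deg, y_deg, x_deg):
    cz, sz = np.cos(np.radians(z_deg)), np.sin(np.radians(z_deg))
    cy, sy = np.cos(np.radians(y_deg)), np.sin(np.radians(y_deg))
    cx, sx = np.cos(np.radians(x_deg)), np.sin(np.radians(x_deg))
    rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    return rz @ ry @ rx


def rotation_zyx_batch(zyx_deg: np.ndarray) -> np.ndarray:
    """Vectorised :func:`rotation_zyx`: ``(n, 3)`` angle triples in degrees
    (columns z, y, x) to an ``(n, 3, 3)`` stack of rotation matrices."""
    a = np.radians(np.asarray(zyx_deg, dtype=float))
    cz, sz = np.cos(a[:, 0]), np.sin(a[:, 0])
    cy, sy = np.cos(a[:, 1]), np.sin(a[:, 1])
    cx, sx = np.cos(a[:, 2]), np.sin(a[:, 2])
    r = np.empty((len(a), 3, 3))
    r[:, 0, 0] = cz * cy
    r[:, 0, 1] = cz * sy * sx - sz * cx
    r[:, 0, 2] = cz * sy * cx + sz * sx
    r[:, 1, 0] = sz * cy
    r[:, 1, 1] = sz * sy * sx + cz * cx
    r[:, 1, 2] = sz * sy * cx - cz * sx
    r[:, 2, 0] = -sy
    r[:, 2, 1] = cy * sx
    r[:, 2, 2] = cy * cx
    return r


# ---------------------------------------------------------------------------
# primitive fitting


def fit_sphere(points: np.ndarray) -> Sphere:
    """Algebraic least-squares sphere through a point cloud.

    Solves the linear system ``2 p·c + k = |p|^2`` for the centre ``c`` and
    ``k = r^2 - |c|^2``. Exact on noiseless samples. Raises on fewer than
    four points or (near-)coplanar input, where the sphere is not unique.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise ValueError("fit_sphere needs at least 4 points of shape (n, 3)")
    scale = max(np.ptp(p, axis=0).max(), 1e-300)
    q = (p - p.mean(axis=0)) / scale
    a = np.column_stack([2.0 * q, np.ones(len(q))])
    b = np.einsum("ij,ij->i", q, q)
    sol, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-8 * sv[0]:
        raise ValueError("points are coplanar or degenerate; sphere fit is ill-conditioned")
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise ValueError("sphere fit degenerate (non-positive squared radius)")
    radius = np.sqrt(r2) * scale
    center = c * scale + p.mean(axis=0)
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - radius) ** 2)))
    return Sphere(center, float(radius), rms)


def fit_cylinder(points: np.ndarray, initial_axis: np.ndarray) -> Cylinder:
    """Least-squares cylinder minimising radial residuals.

    The axis is seeded with ``initial_axis`` (the interactive placement of
    the original workflow is replaced by this required, deterministic seed)
    and refined by nonlinear least squares over a 5-parameter chart: two
    axis-tilt parameters, two in-plane axis-point offsets, and the radius.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 6:
        raise ValueError("fit_cylinder needs at least 6 points of shape (n, 3)")
    d0 = np.asarray(initial_axis, dtype=float)
    nd = np.linalg.norm(d0)
    if nd == 0:
        raise ValueError("initial axis must be nonzero")
    d0 = d0 / nd

    centred = p - p.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise ValueError("points are collinear; cylinder fit is degenerate")

    # orthonormal basis (e1, e2) completing the seed axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d0 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)
    c0 = p.mean(axis=0)
    r0 = float(np.median(np.linalg.norm(_radial(p, c0, d0), axis=1)))

    def unpack(theta):
        t1, t2, o1, o2, r = theta
        d = d0 + t1 * e1 + t2 * e2
        d = d / np.linalg.norm(d)
        c = c0 + o1 * e1 + o2 * e2
        return c, d, r

    def resid(theta):
        c, d, r = unpack(theta)
        return np.linalg.norm(_radial(p, c, d), axis=1) - r

    sol = least_squares(resid, x0=[0.0, 0.0, 0.0, 0.0, r0], method="lm", max_nfev=2000)
    c, d, r = unpack(sol.x)
    if r <= 0:
        raise ValueError("cylinder fit collapsed to non-positive radius")
    # span check: projections along axis and angular arc around it
    axial = (p - c) @ d
    if np.ptp(axial) < 1e-12:
        raise ValueError("points span a single axial position")
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return Cylinder(c, d, float(r), rms)


def _radial(p, c, d):
    v = p - c
    return v - np.outer(v @ d, d)


# ---------------------------------------------------------------------------
# distances


def point_line_distance(p, a, b):
    """Distance from ``p`` to the *infinite* line through ``a`` and ``b``.

    Returns ``(distance, nearest_point)``. The nearest point is the
    orthogonal projection of ``p`` and may fall outside the segment
    ``a``–``b`` — the muscle line of action extends beyond its locators.
    """
    p = np.asarray(p, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    n2 = ab @ ab
    if n2 < 1e-300:
        raise ValueError("line is undefined: a and b coincide")
    t = (p - a) @ ab / n2
    nearest = a + t * ab
    return float(np.linalg.norm(p - nearest)), nearest


# ---------------------------------------------------------------------------
# mesh interpenetration

_TOUCH_TOL = 1e-9


def _require_watertight(mesh: trimesh.Trimesh, name: str) -> None:
    if not isinstance(mesh, trimesh.Trimesh):
        raise TypeError(f"mesh '{name}' must be a trimesh.Trimesh")
    if not mesh.is_watertight:
        raise ValueError(f"mesh '{name}' is not watertight (every edge must be shared by 2 faces)")


def _segment_triangle_hits(p0, seg, v0, e1, e2):
    """Vectorised Moller-Trumbore segment/triangle test over matched rows."""
    h = np.cross(seg, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-14
    if not ok.any():
        return np.zeros(len(p0), dtype=bool)
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    s = p0 - v0
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("ij,ij->i", seg, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    eps = 1e-12
    return ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t >= -eps) & (t <= 1 + eps)


def _candidate_pairs(a: trimesh.Trimesh, b: trimesh.Trimesh):
    ca = a.triangles_center
    cb = b.triangles_center
    ra = np.linalg.norm(a.triangles - ca[:, None, :], axis=2).max(axis=1)
    rb = np.linalg.norm(b.triangles - cb[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cb)
    rmax = rb.max()
    pairs_i = []
    pairs_j = []
    for i, js in enumerate(tree.query_ball_point(ca, r=ra + rmax)):
        if js:
            pairs_i.extend([i] * len(js))
            pairs_j.extend(js)
    if not pairs_i:
        return np.empty(0, int), np.empty(0, int)
    i = np.asarray(pairs_i)
    j = np.asarray(pairs_j)
    close = np.linalg.norm(ca[i] - cb[j], axis=1) <= ra[i] + rb[j]
    return i[close], j[close]


def _edges_cross(tri_a, tri_b):
    """Do any edges of triangles ``tri_a`` cross their paired triangle in
    ``tri_b``? Arrays of shape (m, 3, 3), row-paired."""
    v0 = tri_b[:, 0]
    e1 = tri_b[:, 1] - v0
    e2 = tri_b[:, 2] - v0
    hit = np.zeros(len(tri_a), dtype=bool)
    for k in range(3):
        p0 = tri_a[:, k]
        seg = tri_a[:, (k + 1) % 3] - p0
        hit |= _segment_triangle_hits(p0, seg, v0, e1, e2)
    return hit


def _pairs_touch(tri_a, tri_b, tol):
    """Conservative touching test: any vertex of one triangle within ``tol``
    of the paired triangle's plane patch (vertex-to-triangle distance)."""
    import trimesh.triangles as tt

    for src, dst in ((tri_a, tri_b), (tri_b, tri_a)):
        for k in range(3):
            pts = src[:, k]
            closest = tt.closest_point(dst, pts)
            if (np.linalg.norm(closest - pts, axis=1) <= tol).any():
                return True
    return False


def points_in_mesh(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity containment test for a watertight mesh (odd crossing
    count along a ray means inside). Degenerate ray hits (grazing an edge
    or vertex) are resolved by retrying with a different ray direction."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    scale = float(np.linalg.norm(mesh.extents))
    rng = np.random.default_rng(12345)
    d = np.array([0.5773502691896258, 0.7071067811865476, 0.4082482904638631])
    for _ in range(8):
        d = d / np.linalg.norm(d)
        h = np.cross(d, e2)  # (t, 3)
        det = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        inside = np.zeros(len(pts), dtype=bool)
        degenerate = False
        for i, p in enumerate(pts):
            s = p - v0
            u = np.einsum("ij,ij->i", s, h) * inv
            q = np.cross(s, e1)
            v = np.einsum("j,ij->i", d, q) * inv
            t = np.einsum("ij,ij->i", e2, q) * inv
            hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12 * scale)
            edge_eps = 1e-9
            grazing = hits & (
                (u < edge_eps) | (v < edge_eps) | (u + v > 1 - edge_eps)
            )
            if grazing.any():
                degenerate = True
                break
            inside[i] = (hits.sum() % 2) == 1
        if not degenerate:
            return inside
        d = rng.normal(size=3)
    raise RuntimeError("containment test failed to find a non-degenerate ray")


def meshes_interpenetrate(a: trimesh.Trimesh, b: trimesh.Trimesh,
                          names=("a", "b"), touch_tol: float = _TOUCH_TOL) -> bool:
    """True iff two watertight meshes intersect.

    Covers transversal surface crossings (edge-through-triangle, both
    directions over a KD-tree broad phase), full containment of one mesh in
    the other (ray-parity test), and surface touching within ``touch_tol``
    (touching counts as interpenetration: with a 5° pose grid boundary cases
    are rare and the conservative call is the safer one).
    """
    _require_watertight(a, names[0])
    _require_watertight(b, names[1])

    lo = np.maximum(a.bounds[0], b.bounds[0])
    hi = np.minimum(a.bounds[1], b.bounds[1])
    if np.any(lo - hi > touch_tol):
        return False

    i, j = _candidate_pairs(a, b)
    if len(i):
        tri_a = a.triangles[i]
        tri_b = b.triangles[j]
        if _edges_cross(tri_a, tri_b).any() or _edges_cross(tri_b, tri_a).any():
            return True
        if _pairs_touch(tri_a, tri_b, touch_tol):
            return True

    # no surface crossing: either disjoint or one mesh entirely inside the other
    if points_in_mesh(b, a.vertices[:1]).any() or points_in_mesh(a, b.vertices[:1]).any():
        return True
    return False
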