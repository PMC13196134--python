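"""Cosine-corrected pose space and alpha-shape volumetrics.

Euler-angle space is metrically distorted: with intrinsic z-y-x angles the
invariant (Haar) volume element of the rotation group is cos(y)·dz·dy·dx,
so equal pose-space boxes at different |y| represent unequal amounts of
rotational freedom. The cosine correction applied here rescales the
first-rotation coordinate, zcc = z·cos(y), leaving y and x unchanged, which
locally equalises that volume element and makes alpha-shape volumes in
cubed degrees comparable across joints.

The alpha shape of the corrected viable-pose cloud is the Delaunay
tetrahedralisation filtered to tetrahedra with circumradius <= alpha
(closed inequality); its volume summarises overall joint mobility. The
alpha radius is the larger of a dataset-level floor (default 50°) and the
cloud's critical alpha — the smallest radius at which the shape is one
connected region containing every input point.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError

log = logging.getLogger(__name__)

__all__ = [
    "CorrectedPoseCloud",
    "AlphaShapeResult",
    "ExcursionSummary",
    "cosine_correct",
    "critical_alpha",
    "select_alpha",
    "alpha_shape",
    "pose_space_shape",
    "excursion_summary",
]


@dataclass(frozen=True)
class CorrectedPoseCloud:
    """Cosine-corrected viable poses; columns zcc, ycc, xcc in degrees."""

    points: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("corrected cloud must have shape (n, 3)")
        object.__setattr__(self, "points", p)

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class AlphaShapeResult:
    alpha_radius: float
    critical_alpha: Optional[float]
    volume: float  # cubed degrees
    simplices: np.ndarray  # (t, 4) indices into the point cloud
    points: np.ndarray


@dataclass(frozen=True)
class ExcursionSummary:
    """Per-axis min/max of the cosine-corrected cloud (cc-FE, cc-ABAD, cc-IE)."""

    fe_min: float
    fe_max: float
    abad_min: float
    abad_max: float
    ie_min: float
    ie_max: float

    def as_dict(self):
        return {
            "cc_fe_min": self.fe_min, "cc_fe_max": self.fe_max,
            "cc_abad_min": self.abad_min, "cc_abad_max": self.abad_max,
            "cc_ie_min": self.ie_min, "cc_ie_max": self.ie_max,
        }


def cosine_correct(poses) -> CorrectedPoseCloud:
    """Map (z, y, x) to (z·cos y, y, x), angles in degrees.

    Defined for |y| <= 90; beyond the gimbal singularity the correction has
    no meaning. |zcc| <= |z| always; y and x pass through unchanged.
    """
    p = np.asarray(poses, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if np.any(np.abs(p[:, 1]) > 90.0 + 1e-12):
        raise ValueError("cosine correction undefined for |y| > 90 degrees")
    out = p.copy()
    out[:, 0] = p[:, 0] * np.cos(np.radians(p[:, 1]))
    return CorrectedPoseCloud(out)


def _delaunay(points: np.ndarray) -> Delaunay:
    if len(points) < 4:
        raise ValueError("alpha shape needs at least 4 points")
    try:
        tri = Delaunay(points)
    except QhullError as e:
        raise ValueError(f"degenerate point cloud (coplanar or duplicate points): {e}") from e
    if tri.simplices.size == 0:
        raise ValueError("degenerate point cloud: no tetrahedra")
    return tri


def _tet_metrics(points: np.ndarray, simplices: np.ndarray):
    """Circumradii and volumes of a stack of tetrahedra. Degenerate (flat)
    tetrahedra get infinite circumradius and zero volume."""
    a, b, c, d = (points[simplices[:, k]] for k in range(4))
    u, v, w = b - a, c - a, d - a
    vol6 = np.einsum("ij,ij->i", u, np.cross(v, w))
    volume = np.abs(vol6) / 6.0
    m = np.stack([u, v, w], axis=1)  # (t, 3, 3), rows are the edge vectors
    rhs = 0.5 * np.stack([
        np.einsum("ij,ij->i", u, u),
        np.einsum("ij,ij->i", v, v),
        np.einsum("ij,ij->i", w, w),
    ], axis=1)
    scale = np.linalg.norm(m, axis=(1, 2)) + 1e-300
    ok = np.abs(vol6) > 1e-12 * scale ** 3
    radii = np.full(len(simplices), np.inf)
    if ok.any():
        centre_off = np.linalg.solve(m[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centre_off, axis=1)
    return radii, volume


def alpha_shape(points, alpha_radius: float) -> AlphaShapeResult:
    """Alpha shape of a 3D cloud: Delaunay tetrahedra with circumradius
    <= alpha_radius; volume is the sum of retained tetra volumes (deg³).

    For alpha_radius beyond the maximum circumradius this equals the convex
    hull. Coplanar clouds report volume 0 with a warning (mirroring the
    exclusion workflow for degenerate joints) rather than raising.
    """
    pts = _cloud_points(points)
    if alpha_radius <= 0:
        raise ValueError("alpha radius must be positive")
    try:
        tri = _delaunay(pts)
    except ValueError as e:
        if len(pts) >= 4 and "degenerate" in str(e) and _is_coplanar(pts):
            warnings.warn("coplanar pose cloud: alpha-shape volume reported as 0")
            return AlphaShapeResult(alpha_radius, None, 0.0, np.empty((0, 4), int), pts)
        raise
    radii, volume = _tet_metrics(pts, tri.simplices)
    keep = radii <= alpha_radius
    return AlphaShapeResult(
        float(alpha_radius), None, float(volume[keep].sum()),
        tri.simplices[keep], pts,
    )


def _is_coplanar(points, tol=1e-9):
    c = points - points.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    return sv[-1] < tol * max(sv[0], 1e-300)


def _cloud_points(points) -> np.ndarray:
    if isinstance(points, CorrectedPoseCloud):
        return points.points
    return np.asarray(points, dtype=float)


def critical_alpha(points) -> float:
    """Smallest alpha for which the alpha shape is a single connected region
    containing all input points.

    Bisects over the sorted set of tetrahedron circumradii; both the
    all-points and the one-region condition are monotone in alpha, with
    region connectivity taken across shared triangular faces.
    """
    pts = _cloud_points(points)
    tri = _delaunay(pts)
    radii, _ = _tet_metrics(pts, tri.simplices)
    finite = np.isfinite(radii)
    if not finite.any():
        raise ValueError("degenerate point cloud: all tetrahedra are flat")
    candidates = np.unique(radii[finite])

    n_points = len(pts)
    simplices = tri.simplices
    neigh = tri.neighbors

    def ok(alpha):
        keep = radii <= alpha
        if not keep.any():
            return False
        if len(np.unique(simplices[keep])) < n_points:
            return False
        idx = np.full(len(simplices), -1)
        kept_ids = np.flatnonzero(keep)
        idx[kept_ids] = np.arange(len(kept_ids))
        rows, cols = [], []
        for k in range(4):
            nb = neigh[kept_ids, k]
            valid = (nb >= 0) & keep[np.maximum(nb, 0)]
            rows.append(idx[kept_ids[valid]])
            cols.append(idx[nb[valid]])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(kept_ids), len(kept_ids)))
        ncomp, _ = connected_components(g, directed=False)
        return ncomp == 1

    lo, hi = 0, len(candidates) - 1
    if not ok(candidates[hi]):
        raise ValueError("no alpha makes the shape one region containing all points")
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def select_alpha(points, floor: float = 50.0) -> float:
    """Alpha radius used for the pose-space shape: the dataset floor unless
    the cloud's critical alpha surpasses it, in which case the critical
    value is used instead."""
    return max(float(floor), critical_alpha(points))


def pose_space_shape(points, floor: float = 50.0) -> AlphaShapeResult:
    """Convenience wrapper: select the alpha radius (floor rule) and build
    the alpha shape, recording both radii in the result."""
    crit = critical_alpha(points)
    alpha = max(float(floor), crit)
    res = alpha_shape(points, alpha)
    return AlphaShapeResult(res.alpha_radius, crit, res.volume, res.simplices, res.points)


def excursion_summary(points) -> ExcursionSummary:
    """Per-axis minima and maxima of the corrected pose cloud."""
    pts = _cloud_points(points)
    if len(pts) == 0:
        raise ValueError("empty pose cloud")
    mins = pts.min(axis=0)
    maxs = pts.max(axis=0)
    return ExcursionSummary(
        float(mins[0]), float(maxs[0]),
        float(mins[1]), float(maxs[1]),
        float(mins[2]), float(maxs[2]),
    )
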