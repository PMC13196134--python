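"""Accelerated collision machinery for dense pose sweeps.

A 75,295-cell pose grid evaluated against two bone meshes is far too large
for per-pose exact triangle intersection, so the sweep uses a voxel
occupancy predicate: each watertight mesh is rasterised once into a cubic
voxel grid whose cells are classified interior / boundary / exterior
(boundary = cells near a triangle's plane within its bounding box;
exterior by flood fill from the grid border). A pose collides when any
sample point of one bone (vertices plus face centroids) lands in a
strictly interior cell of the other, tested in both directions.

Collisions therefore register once penetration exceeds the boundary-shell
thickness (about one voxel): the predicate is neutral within a voxel of
the surface, and its spatial error is bounded by roughly two voxels, which
at the default resolution stays below the 5° grid step for joint-scale
geometry. The per-pose exact predicate (`engine="exact"` in the sweep)
remains the reference semantics, where touching counts as collision.

The inner loop is JIT-compiled with numba when available and falls back to
chunked numpy otherwise.
"""
from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["VoxelOccupancy", "sweep_codes"]


class VoxelOccupancy:
    """Conservative inside-or-boundary voxelisation of a watertight mesh."""

    def __init__(self, mesh: trimesh.Trimesh, resolution: int = 96):
        if resolution < 8:
            raise ValueError("voxel resolution must be at least 8")
        lo, hi = mesh.bounds
        extent = hi - lo
        pitch = float(extent.max()) / (resolution - 4)
        shape = np.ceil(extent / pitch).astype(int) + 5
        origin = lo - 2.0 * pitch

        boundary = np.zeros(shape, dtype=bool)
        tri = mesh.triangles
        lo_idx = np.floor((tri.min(axis=1) - origin) / pitch).astype(int)
        hi_idx = np.floor((tri.max(axis=1) - origin) / pitch).astype(int)
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(normals, axis=1)
        # box-plane overlap radius: projection of the half cell diagonal
        half = 0.5 * pitch
        for t in range(len(tri)):
            i0, j0, k0 = lo_idx[t]
            i1, j1, k1 = hi_idx[t]
            if nrm[t] < 1e-12:
                boundary[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] = True
                continue
            n = normals[t] / nrm[t]
            r_box = half * (abs(n[0]) + abs(n[1]) + abs(n[2]))
            cx = origin[0] + (np.arange(i0, i1 + 1) + 0.5) * pitch
            cy = origin[1] + (np.arange(j0, j1 + 1) + 0.5) * pitch
            cz = origin[2] + (np.arange(k0, k1 + 1) + 0.5) * pitch
            d = (n[0] * (cx[:, None, None] - tri[t, 0, 0])
                 + n[1] * (cy[None, :, None] - tri[t, 0, 1])
                 + n[2] * (cz[None, None, :] - tri[t, 0, 2]))
            boundary[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] |= np.abs(d) <= r_box + 1e-12

        open_cells, nlab = ndimage.label(~boundary)
        border_labels = np.unique(
            np.concatenate([
                open_cells[0].ravel(), open_cells[-1].ravel(),
                open_cells[:, 0].ravel(), open_cells[:, -1].ravel(),
                open_cells[:, :, 0].ravel(), open_cells[:, :, -1].ravel(),
            ])
        )
        outside = np.isin(open_cells, border_labels[border_labels > 0])
        # occupancy = strictly interior cells: a sample registers a collision
        # once it penetrates past the boundary shell (about one voxel), so
        # the predicate is neutral within a voxel of the surface instead of
        # flagging the interarticular gap itself
        self.occupied = (~boundary & ~outside).astype(np.uint8)
        self.boundary = boundary
        self.origin = origin
        self.pitch = pitch
        self.shape = np.asarray(shape)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Occupancy lookup for an (n, 3) array of points."""
        idx = np.floor((np.asarray(points, float) - self.origin) / self.pitch).astype(int)
        ok = np.all((idx >= 0) & (idx < self.shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.occupied[sel[:, 0], sel[:, 1], sel[:, 2]].astype(bool)
        return out


def _sweep_numpy(rots, cor, pts_d, occ_p, orig_p, pitch_p, pts_p, occ_d, orig_d, pitch_d):
    n = len(rots)
    codes = np.ones(n, dtype=np.uint8)
    shape_p = np.asarray(occ_p.shape)
    shape_d = np.asarray(occ_d.shape)
    chunk = max(1, int(2e7 // max(len(pts_d), 1)))
    for s in range(0, n, chunk):
        r = rots[s:s + chunk]
        # distal samples (COR-relative) into the proximal grid
        posed = np.einsum("pij,nj->pni", r, pts_d) + cor
        idx = np.floor((posed - orig_p) / pitch_p).astype(int)
        inb = np.all((idx >= 0) & (idx < shape_p), axis=2)
        hit = np.zeros(inb.shape, dtype=bool)
        ii = idx[inb]
        hit[inb] = occ_p[ii[:, 0], ii[:, 1], ii[:, 2]].astype(bool)
        collide = hit.any(axis=1)
        # proximal samples into the reference-pose distal grid (inverse rotation)
        posed = np.einsum("pji,nj->pni", r, pts_p) + cor
        idx = np.floor((posed - orig_d) / pitch_d).astype(int)
        inb = np.all((idx >= 0) & (idx < shape_d), axis=2)
        hit = np.zeros(inb.shape, dtype=bool)
        ii = idx[inb]
        hit[inb] = occ_d[ii[:, 0], ii[:, 1], ii[:, 2]].astype(bool)
        collide |= hit.any(axis=1)
        codes[s:s + chunk] = (~collide).astype(np.uint8)
    return codes


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _sweep_numba(rots, cor, pts_d, occ_p, orig_p, pitch_p, pts_p, occ_d, orig_d, pitch_d):  # pragma: no cover - jitted
        n = rots.shape[0]
        codes = np.ones(n, dtype=np.uint8)
        sp0, sp1, sp2 = occ_p.shape
        sd0, sd1, sd2 = occ_d.shape
        for p in range(n):
            r = rots[p]
            collide = False
            for m in range(pts_d.shape[0]):
                x = r[0, 0] * pts_d[m, 0] + r[0, 1] * pts_d[m, 1] + r[0, 2] * pts_d[m, 2] + cor[0]
                y = r[1, 0] * pts_d[m, 0] + r[1, 1] * pts_d[m, 1] + r[1, 2] * pts_d[m, 2] + cor[1]
                z = r[2, 0] * pts_d[m, 0] + r[2, 1] * pts_d[m, 1] + r[2, 2] * pts_d[m, 2] + cor[2]
                i = int(np.floor((x - orig_p[0]) / pitch_p))
                j = int(np.floor((y - orig_p[1]) / pitch_p))
                k = int(np.floor((z - orig_p[2]) / pitch_p))
                if 0 <= i < sp0 and 0 <= j < sp1 and 0 <= k < sp2 and occ_p[i, j, k]:
                    collide = True
                    break
            if not collide:
                for m in range(pts_p.shape[0]):
                    # inverse rotation (transpose) of proximal samples into distal frame
                    x = r[0, 0] * pts_p[m, 0] + r[1, 0] * pts_p[m, 1] + r[2, 0] * pts_p[m, 2] + cor[0]
                    y = r[0, 1] * pts_p[m, 0] + r[1, 1] * pts_p[m, 1] + r[2, 1] * pts_p[m, 2] + cor[1]
                    z = r[0, 2] * pts_p[m, 0] + r[1, 2] * pts_p[m, 1] + r[2, 2] * pts_p[m, 2] + cor[2]
                    i = int(np.floor((x - orig_d[0]) / pitch_d))
                    j = int(np.floor((y - orig_d[1]) / pitch_d))
                    k = int(np.floor((z - orig_d[2]) / pitch_d))
                    if 0 <= i < sd0 and 0 <= j < sd1 and 0 <= k < sd2 and occ_d[i, j, k]:
                        collide = True
                        break
            if collide:
                codes[p] = 0
        return codes


def sweep_codes(rotations: np.ndarray, cor: np.ndarray,
                distal_samples: np.ndarray, proximal_grid: VoxelOccupancy,
                proximal_samples: np.ndarray, distal_grid: VoxelOccupancy) -> np.ndarray:
    """Viability codes (1 = no collision) for a stack of world rotations.

    ``distal_samples`` are COR-relative sample points of the distal bone in
    its reference pose; ``proximal_samples`` are COR-relative sample points
    of the fixed proximal bone. ``rotations`` are world rotation matrices
    about the COR, shape (n, 3, 3).
    """
    rotations = np.ascontiguousarray(rotations, dtype=np.float64)
    cor = np.ascontiguousarray(cor, dtype=np.float64)
    pts_d = np.ascontiguousarray(distal_samples, dtype=np.float64)
    pts_p = np.ascontiguousarray(proximal_samples, dtype=np.float64)
    args = (
        rotations, cor,
        pts_d, proximal_grid.occupied, proximal_grid.origin.astype(np.float64),
        float(proximal_grid.pitch),
        pts_p, distal_grid.occupied, distal_grid.origin.astype(np.float64),
        float(distal_grid.pitch),
    )
    if _HAVE_NUMBA:
        return _sweep_numba(*args)
    return _sweep_numpy(*args)
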