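"""Metatarsal torsion: rotation of the bone's head about its long axis.

Two cylinders are fitted — one to the curvature of the metatarsal head
(axis parallel to the sesamoids) and one to the concavity of the distal
articular surface — and a coordinate frame is placed at the centroid of the
proximal and distal articular surfaces, both sharing the long-axis x
direction (centroid-to-centroid). Which frame axis follows which cylinder
axis is clade-specific: in rodents and tree shrews the distal z and
proximal y track the cylinders; in primates and marsupials the distal y and
proximal z do. Torsion (angle alpha) is the unsigned rotation about x
carrying one frame's transverse axes onto the other's, reported in
[0, 180).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh

from graspmorph.geometry import Cylinder, Frame
from graspmorph.rig import Convention

__all__ = [
    "ArticularPatch",
    "TorsionResult",
    "patch_area",
    "build_epiphysis_frames",
    "torsion_angle",
]

_DEGENERATE_AXIS_DEG = 5.0


@dataclass
class ArticularPatch:
    """A subset of mesh faces forming an articular surface."""

    mesh: trimesh.Trimesh
    faces: Optional[np.ndarray] = None  # face indices; None = all faces

    def __post_init__(self):
        if self.faces is None:
            self.faces = np.arange(len(self.mesh.faces))
        self.faces = np.asarray(self.faces, dtype=int)
        if len(self.faces) == 0:
            raise ValueError("articular patch has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.mesh.faces):
            raise ValueError("patch face indices out of range")

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.triangles[self.faces]

    @property
    def areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted centroid of the patch."""
        a = self.areas
        centres = self.triangles.mean(axis=1)
        return (centres * a[:, None]).sum(axis=0) / a.sum()


@dataclass(frozen=True)
class TorsionResult:
    alpha_deg: float
    proximal_frame: Frame
    distal_frame: Frame
    proximal_area: float
    distal_area: float


def patch_area(patch: ArticularPatch) -> float:
    """Total area of the patch (sum of triangle areas), mm²."""
    return float(patch.areas.sum())


def _project_off_axis(v: np.ndarray, x: np.ndarray, label: str) -> np.ndarray:
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    angle = np.degrees(np.arccos(np.clip(abs(v @ x), -1.0, 1.0)))
    if angle < _DEGENERATE_AXIS_DEG:
        raise ValueError(
            f"{label} cylinder axis within {_DEGENERATE_AXIS_DEG} deg of the long axis; "
            "projection is degenerate"
        )
    w = v - x * (x @ v)
    return w / np.linalg.norm(w)


def build_epiphysis_frames(proximal_patch: ArticularPatch, distal_patch: ArticularPatch,
                           head_cylinder: Cylinder, proximal_cylinder: Cylinder,
                           convention: Convention):
    """Coordinate frames on the two epiphyses sharing the long-axis x.

    Frame origins sit at the patch centroids; x runs from the proximal to
    the distal centroid; the remaining axes come from the cylinder axes
    projected orthogonal to x and completed right-handedly, per the clade
    convention described in the module docstring.
    """
    op = proximal_patch.centroid
    od = distal_patch.centroid
    x = od - op
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("patch centroids coincide; long axis undefined")
    x = x / nx

    head_axis = _project_off_axis(head_cylinder.axis_direction, x, "distal (head)")
    prox_axis = _project_off_axis(proximal_cylinder.axis_direction, x, "proximal")

    convention = Convention(convention)
    if convention is Convention.RODENT_SCANDENTIAN:
        # distal z follows the head cylinder, proximal y the proximal cylinder
        zd = head_axis
        yd = np.cross(zd, x)
        distal = Frame(od, np.column_stack([x, yd, zd]))
        yp = prox_axis
        zp = np.cross(x, yp)
        proximal = Frame(op, np.column_stack([x, yp, zp]))
    else:
        # primates and marsupials: distal y follows the head cylinder,
        # proximal z the proximal cylinder
        yd = head_axis
        zd = np.cross(x, yd)
        distal = Frame(od, np.column_stack([x, yd, zd]))
        zp = prox_axis
        yp = np.cross(zp, x)
        proximal = Frame(op, np.column_stack([x, yp, zp]))
    return proximal, distal


def torsion_angle(proximal_frame: Frame, distal_frame: Frame) -> float:
    """Unsigned rotation about the shared x axis between the two frames,
    degrees in [0, 180)."""
    xp = proximal_frame.axis_x
    xd = distal_frame.axis_x
    if abs(np.clip(xp @ xd, -1, 1)) < np.cos(np.radians(1e-3)):
        raise ValueError("frames do not share an x direction")
    yp = proximal_frame.axis_y
    yd = distal_frame.axis_y
    cos_a = np.clip(yp @ yd, -1.0, 1.0)
    sin_a = np.clip(xp @ np.cross(yp, yd), -1.0, 1.0)
    alpha = abs(np.degrees(np.arctan2(sin_a, cos_a)))
    return 0.0 if alpha >= 180.0 else float(alpha)
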