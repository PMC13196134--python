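"""Instantaneous muscle moment arms (IMMAs) about the joint centre of rotation.

A muscle is modelled as the infinite straight line through its origin
locator (fixed with the proximal bone) and insertion locator (carried by
the distal bone through every pose) — no via-points or wrapping. The IMMA
at a pose is the perpendicular distance from the COR to that line; the
nearest point may fall outside the origin–insertion segment.

Model-unit moment arms are converted to millimetres with the specimen/model
scale ratio measured between the calcaneal tuberosity and the fifth
metatarso-phalangeal joint, IMMA(mm) = a(mm)/b(model units) · IMMA(model
units), and normalised by muscle length to a unitless index for
cross-species comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from graspmorph.geometry import point_line_distance
from graspmorph.posespace import CorrectedPoseCloud
from graspmorph.rig import JointModel, PoseViabilityTable

__all__ = [
    "MusclePath",
    "ScaleFactor",
    "imma_at_pose",
    "scale_imma",
    "normalize_imma",
    "imma_field",
]


@dataclass(frozen=True)
class MusclePath:
    """Origin/insertion attachment points (reference-pose world coordinates)
    plus the muscle length used for normalisation."""

    name: str
    origin: np.ndarray  # bound to the fixed proximal frame
    insertion: np.ndarray  # bound to the mobile distal bone
    muscle_length: Optional[float] = None  # mm

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, dtype=float))
        if self.muscle_length is not None and not self.muscle_length > 0:
            raise ValueError("muscle length must be positive")


@dataclass(frozen=True)
class ScaleFactor:
    """Specimen-to-model scale: the calcaneal tuberosity to fifth
    metatarso-phalangeal distance on the specimen (a, mm) and on the model
    (b, model units)."""

    a_mm: float
    b_model: float

    def __post_init__(self):
        if not (self.a_mm > 0 and self.b_model > 0):
            raise ValueError("scale lengths must be positive")

    @property
    def mm_per_unit(self) -> float:
        return self.a_mm / self.b_model


def _posed_insertion(model: JointModel, muscle: MusclePath, pose_zyx_deg) -> np.ndarray:
    w = model.world_rotation(pose_zyx_deg)
    return model.cor + w @ (muscle.insertion - model.cor)


def imma_at_pose(model: JointModel, muscle: MusclePath, pose_zyx_deg) -> float:
    """Moment arm (model units) at one pose: distance from the COR to the
    line through the fixed origin and the pose-carried insertion."""
    ins = _posed_insertion(model, muscle, pose_zyx_deg)
    if np.linalg.norm(ins - muscle.origin) < 1e-12:
        raise ValueError(f"muscle '{muscle.name}': origin and insertion coincide at this pose")
    d, _ = point_line_distance(model.cor, muscle.origin, ins)
    return d


def scale_imma(imma_model_units: float, scale: ScaleFactor) -> float:
    """Convert a moment arm from model units to millimetres."""
    return scale.mm_per_unit * imma_model_units


def normalize_imma(imma_mm: float, muscle_length_mm: float) -> float:
    """Length-normalised (unitless) moment arm."""
    if not muscle_length_mm > 0:
        raise ValueError("muscle length must be positive")
    return imma_mm / muscle_length_mm


def imma_field(model: JointModel, muscle: MusclePath, table: PoseViabilityTable,
               scale: ScaleFactor, corrected: Optional[CorrectedPoseCloud] = None,
               muscle_length_mm: Optional[float] = None):
    """IMMA at every viable, non-disarticulated pose.

    Returns ``(records, argmax_poses)``: a dataframe with pose angles,
    corrected coordinates (when supplied), and the moment arm in model
    units, mm and length-normalised form; and the pose(s) attaining the
    maximum normalised IMMA (all ties reported).
    """
    viable = table.viable
    if len(viable) == 0:
        raise ValueError("no viable poses to evaluate")
    length = muscle_length_mm if muscle_length_mm is not None else muscle.muscle_length
    if length is None or not length > 0:
        raise ValueError("a positive muscle length is required for normalisation")

    poses = viable[["z_deg", "y_deg", "x_deg"]].to_numpy()
    rots = model.world_rotation_batch(poses)
    ins = model.cor + np.einsum("pij,j->pi", rots, muscle.insertion - model.cor)
    o = muscle.origin
    ab = ins - o
    norms = np.linalg.norm(ab, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError(f"muscle '{muscle.name}': origin and insertion coincide at some pose")
    cross = np.cross(np.broadcast_to(model.cor - o, ab.shape), ab)
    imma_model = np.linalg.norm(cross, axis=1) / norms
    imma_mm = scale.mm_per_unit * imma_model
    imma_norm = imma_mm / length

    records = pd.DataFrame({
        "z_deg": poses[:, 0], "y_deg": poses[:, 1], "x_deg": poses[:, 2],
        "imma_model": imma_model, "imma_mm": imma_mm, "imma_norm": imma_norm,
    })
    if corrected is not None:
        if len(corrected) != len(records):
            raise ValueError("corrected cloud does not match the viable pose count")
        records[["zcc", "ycc", "xcc"]] = corrected.points
        records = records[["z_deg", "y_deg", "x_deg", "zcc", "ycc", "xcc",
                           "imma_model", "imma_mm", "imma_norm"]]

    best = records["imma_norm"].max()
    ties = records[np.isclose(records["imma_norm"], best, rtol=1e-12, atol=1e-12)]
    argmax_poses = ties[["z_deg", "y_deg", "x_deg"]].to_numpy()
    return records, argmax_poses
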