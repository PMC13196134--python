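"""File interfaces: meshes (PLY/STL/OBJ), landmark tables, results."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = ["load_mesh", "save_mesh", "read_landmarks", "write_landmarks"]

_LANDMARK_COLUMNS = ["specimen", "structure", "x", "y", "z"]


def load_mesh(path) -> trimesh.Trimesh:
    """Load a triangle mesh (PLY, STL or OBJ, binary or ASCII)."""
    mesh = trimesh.load(str(path), force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: not a triangle mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


def read_landmarks(path) -> pd.DataFrame:
    """Landmark point sets: CSV with columns specimen, structure, x, y, z (mm)."""
    df = pd.read_csv(path)
    missing = set(_LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark file {path} missing columns {sorted(missing)}")
    if not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy(float))):
        raise ValueError(f"landmark file {path} contains non-finite coordinates")
    return df[_LANDMARK_COLUMNS + [c for c in df.columns if c not in _LANDMARK_COLUMNS]]


def write_landmarks(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def landmark_points(df: pd.DataFrame, structure: str, specimen=None) -> np.ndarray:
    """Extract the (n, 3) point set of one structure (optionally filtered by
    specimen) from a landmark table."""
    sel = df[df["structure"] == structure]
    if specimen is not None:
        sel = sel[sel["specimen"] == specimen]
    if len(sel) == 0:
        raise KeyError(f"no landmarks for structure '{structure}'")
    return sel[["x", "y", "z"]].to_numpy(float)
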