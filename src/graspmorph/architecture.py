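"""Muscle architecture: storage-corrected volume, length, ACSA and
body-mass-normalised indices.

Muscle volumes segmented from fluid-stored specimens shrink with storage,
so multiplicative corrections are applied before any comparison: x1.64 for
short-term ethanol storage, x2.49 for long-term ethanol storage, and x1.32
for more than a month in ~4% formalin; a specimen can carry the formalin
factor on top of an ethanol one, and the factors compose multiplicatively.

The anatomical cross-sectional area is ACSA = TotVolume / TotLength, a
proxy for force-generating capacity that ignores pennation. Where a metric
correlates with body mass across species (Pearson test), values are
normalised assuming isometric scaling: volume / mass, length / mass^0.33,
ACSA / mass^0.66 (exponents used verbatim, as printed in comparative
datasets of this kind).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "STORAGE_FACTORS",
    "PreservationState",
    "ArchitectureResult",
    "corrected_volume",
    "muscle_length",
    "acsa",
    "normalize_by_mass",
    "correlation_gate",
    "architecture_result",
]

STORAGE_FACTORS = {
    "ethanol_short": 1.64,
    "ethanol_long": 2.49,
    "formalin_month": 1.32,
}

_VALID_EXPONENTS = (1.0, 0.33, 0.66)


@dataclass(frozen=True)
class PreservationState:
    """Set of storage-condition flags; the two ethanol durations are
    mutually exclusive."""

    flags: frozenset

    def __init__(self, flags: Iterable[str] = ()):
        fs = frozenset(flags)
        unknown = fs - set(STORAGE_FACTORS)
        if unknown:
            raise ValueError(f"unknown preservation flags: {sorted(unknown)}")
        if {"ethanol_short", "ethanol_long"} <= fs:
            raise ValueError("ethanol_short and ethanol_long are mutually exclusive")
        object.__setattr__(self, "flags", fs)

    @property
    def factor(self) -> float:
        f = 1.0
        for flag in self.flags:
            f *= STORAGE_FACTORS[flag]
        return f


@dataclass(frozen=True)
class ArchitectureResult:
    """Corrected architecture of one muscle in one specimen, with the
    mass-normalised forms used for cross-species comparison."""

    corrected_volume_mm3: float
    length_mm: float
    acsa_mm2: float
    rel_volume: float  # mm³/g
    rel_length: float  # mm/g^0.33
    rel_acsa: float  # mm²/g^0.66


def corrected_volume(raw_volume_mm3: float, preservation: PreservationState) -> float:
    """Storage-corrected muscle volume (mm³): the raw segmented volume times
    the product of the applicable storage factors."""
    if not raw_volume_mm3 > 0:
        raise ValueError("raw volume must be positive")
    if not isinstance(preservation, PreservationState):
        preservation = PreservationState(preservation)
    return raw_volume_mm3 * preservation.factor


def muscle_length(belly_chains: Sequence[np.ndarray]) -> float:
    """Muscle length (mm) from per-belly endpoint chains.

    Each chain holds 2 points (straight belly, endpoint distance) or 3
    points (curved belly: a midpoint landmark splits the measurement and
    the two distances are added). Multi-belly muscles report the mean over
    bellies.
    """
    if len(belly_chains) == 0:
        raise ValueError("at least one belly chain required")
    lengths = []
    for chain in belly_chains:
        pts = np.asarray(chain, dtype=float)
        if pts.ndim != 2 or pts.shape[0] not in (2, 3) or pts.shape[1] != 3:
            raise ValueError("each belly chain must hold 2 or 3 points of dimension 3")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ValueError("duplicate consecutive points in a belly chain")
        lengths.append(seg.sum())
    return float(np.mean(lengths))


def acsa(corrected_volume_mm3: float, length_mm: float) -> float:
    """Anatomical cross-sectional area, ACSA = TotVolume / TotLength (mm²)."""
    if not length_mm > 0:
        raise ValueError("muscle length must be positive")
    return corrected_volume_mm3 / length_mm


def normalize_by_mass(value: float, body_mass_g: float, exponent: float) -> float:
    """Isometric body-mass normalisation: value / mass^exponent with
    exponent 1 (volume), 0.33 (length) or 0.66 (ACSA)."""
    if not body_mass_g > 0:
        raise ValueError("body mass must be positive")
    if exponent not in _VALID_EXPONENTS:
        raise ValueError(f"exponent must be one of {_VALID_EXPONENTS}")
    return value / body_mass_g ** exponent


def correlation_gate(values: Sequence[float], masses: Sequence[float],
                     alpha_level: float = 0.05):
    """Pearson test deciding whether a metric is normalised by body mass.

    Returns ``(r, p, normalize)`` with ``normalize = (p < alpha_level)``.
    Requires at least 3 paired observations with nonzero variance on both
    sides (applied to muscles present in more than two species).
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.shape != m.shape or v.ndim != 1 or len(v) < 3:
        raise ValueError("correlation gate needs >= 3 paired observations")
    if np.std(v) == 0 or np.std(m) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = stats.pearsonr(v, m)
    return float(r), float(p), bool(p < alpha_level)


def architecture_result(raw_volume_mm3: float, preservation,
                        belly_chains: Sequence[np.ndarray],
                        body_mass_g: float) -> ArchitectureResult:
    """Full per-muscle chain: storage correction, length, ACSA and the three
    mass-normalised indices."""
    vol = corrected_volume(raw_volume_mm3, preservation)
    length = muscle_length(belly_chains)
    area = acsa(vol, length)
    return ArchitectureResult(
        corrected_volume_mm3=vol,
        length_mm=length,
        acsa_mm2=area,
        rel_volume=normalize_by_mass(vol, body_mass_g, 1.0),
        rel_length=normalize_by_mass(length, body_mass_g, 0.33),
        rel_acsa=normalize_by_mass(area, body_mass_g, 0.66),
    )
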