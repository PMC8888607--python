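"""Volume → mass conversion and mass normalisations.

Muscle mass is computed from mesh volume at an assumed homogeneous fresh
muscle tissue density of 1060 kg/m³; tendon, where partitioned out, is
about 5% denser (1120 kg/m³).  The muscle/tendon partition is always an
input — it is never inferred from geometry — and the default is all-muscle.

Two normalisations support cross-specimen comparison of mass estimates:
dividing by body mass (dimensionless M_muscle/M_body) and dividing by the
median of a per-muscle set of reference measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh_core import UNIT_TO_M

__all__ = [
    "MUSCLE_DENSITY",
    "TENDON_DENSITY",
    "MassParams",
    "MuscleRecord",
    "volume_to_m3",
    "mass_from_volume",
    "composite_mass",
    "normalize_by_body_mass",
    "normalize_by_reference_median",
]

MUSCLE_DENSITY = 1060.0  # kg/m³, fresh muscle tissue
TENDON_DENSITY = 1120.0  # kg/m³, tendon (~5% denser)


@dataclass(frozen=True)
class MassParams:
    muscle_density: float = MUSCLE_DENSITY
    tendon_density: float = TENDON_DENSITY

    def __post_init__(self):
        if self.muscle_density <= 0 or self.tendon_density <= 0:
            raise ValueError("densities must be positive")


@dataclass(frozen=True)
class MuscleRecord:
    """A named muscle with volume, mass, and optional normalised mass."""

    name: str
    volume: float
    unit: str
    mass: float
    body_mass: float | None = None
    normalized_mass: float | None = None


def volume_to_m3(volume: float, unit: str) -> float:
    """Convert a volume in model-units³ (mm/cm/m tag) to m³."""
    if unit not in UNIT_TO_M:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(UNIT_TO_M)}")
    return float(volume) * UNIT_TO_M[unit] ** 3


def mass_from_volume(volume: float, unit: str = "m", params: MassParams = MassParams()) -> float:
    """Mass in kg of a muscle volume at the homogeneous muscle density."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return volume_to_m3(volume, unit) * params.muscle_density


def composite_mass(
    muscle_volume: float,
    tendon_volume: float,
    unit: str = "m",
    params: MassParams = MassParams(),
) -> float:
    """Mass of a muscle–tendon unit with an explicit muscle/tendon partition."""
    if muscle_volume < 0 or tendon_volume < 0:
        raise ValueError("volumes must be >= 0")
    return (
        volume_to_m3(muscle_volume, unit) * params.muscle_density
        + volume_to_m3(tendon_volume, unit) * params.tendon_density
    )


def normalize_by_body_mass(record: MuscleRecord, body_mass: float) -> MuscleRecord:
    """Return a record with normalized_mass = mass / body_mass (dimensionless)."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    return replace(record, body_mass=float(body_mass), normalized_mass=record.mass / body_mass)


def normalize_by_reference_median(value: float, reference) -> float:
    """Divide a value by the median of a non-empty set of reference values.

    For an even number of reference values the median is the mean of the
    two middle order statistics.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference set is empty")
    med = float(np.median(reference))
    if med == 0:
        raise ValueError("reference median is zero")
    return float(value) / med
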