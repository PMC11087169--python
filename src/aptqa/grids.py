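"""Voxel containers: dose fields, structure masks and prescriptions.

All geometry is axis-aligned.  A grid is described by its voxel value
array (indexed ``[ix, iy, iz]``), the voxel edge lengths ``spacing`` in
mm, and the physical position ``origin`` (mm) of the *center* of voxel
``(0, 0, 0)``.  Doses are in Gy-RBE throughout (physical dose times the
constant proton RBE of 1.1).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "DoseGrid",
    "StructureMask",
    "Prescription",
    "CongruenceError",
    "StructureAbsentError",
    "TARGET_STRUCTURES",
    "OAR_STRUCTURES",
    "STRUCTURES",
]

# Canonical structure names, in the column order of the endpoint tables.
TARGET_STRUCTURES = ("CTV-High", "CTV-Mid", "CTV-Low")
OAR_STRUCTURES = ("Right Parotid", "Left Parotid", "Oral Cavity", "Brainstem", "Spinal Cord")
STRUCTURES = TARGET_STRUCTURES + OAR_STRUCTURES


class CongruenceError(ValueError):
    """Two voxel objects do not share the same grid frame."""


class StructureAbsentError(ValueError):
    """An operation requires a nonempty structure mask."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D scalar dose field on an axis-aligned voxel grid.

    Parameters
    ----------
    values
        Dose per voxel in Gy-RBE; finite and non-negative.
    spacing
        Voxel edge lengths in mm along each axis, all positive.
    origin
        Physical position (mm) of the center of the first voxel.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"dose grid must be 3-D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose grid contains non-finite values")
        if values.size and values.min() < 0:
            raise ValueError("dose grid contains negative dose")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {spacing}")
        if len(origin) != 3:
            raise ValueError("origin must have three components")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates along each axis (mm)."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )  # type: ignore[return-value]

    def same_frame(self, other: "DoseGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """A new grid on the same frame with different voxel values."""
        return DoseGrid(values, self.spacing, self.origin)

    def empty_like(self) -> "DoseGrid":
        return self.with_values(np.zeros(self.shape))


@dataclass(frozen=True)
class StructureMask:
    """A boolean voxel field naming a CTV level or an organ at risk."""

    name: str
    mask: np.ndarray
    role: str = "oar"  # "target" | "oar"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask.astype(bool)
        if mask.ndim != 3:
            raise ValueError(f"structure mask must be 3-D, got ndim={mask.ndim}")
        if self.role not in ("target", "oar"):
            raise ValueError(f"role must be 'target' or 'oar', got {self.role!r}")
        object.__setattr__(self, "mask", mask)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_cc(self, grid: DoseGrid) -> float:
        """Structure volume in cm^3 on the given grid frame."""
        return self.voxel_count * grid.voxel_volume_cc


def require_congruent(dose: DoseGrid, mask: StructureMask) -> None:
    if mask.mask.shape != dose.shape:
        raise CongruenceError(
            f"structure {mask.name!r} shape {mask.mask.shape} does not match "
            f"dose grid shape {dose.shape}"
        )
    if mask.is_empty:
        raise StructureAbsentError(f"structure {mask.name!r} is empty/absent")


@dataclass(frozen=True)
class Prescription:
    """Per-target prescription dose levels (Gy-RBE) and fraction count.

    Levels must be positive and ordered CTV-High >= CTV-Mid >= CTV-Low
    where present; targets absent from a patient simply have no entry.
    """

    levels: Mapping[str, float]
    n_fractions: int = 35

    def __post_init__(self) -> None:
        levels = dict(self.levels)
        for name, dose in levels.items():
            if name not in TARGET_STRUCTURES:
                raise ValueError(f"unknown target level {name!r}")
            if not (np.isfinite(dose) and dose > 0):
                raise ValueError(f"prescription for {name} must be positive, got {dose}")
        ordered = [levels[n] for n in TARGET_STRUCTURES if n in levels]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"prescription levels must be non-increasing High>=Mid>=Low: {levels}")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        object.__setattr__(self, "levels", levels)

    def level_for(self, structure: str) -> float:
        try:
            return self.levels[structure]
        except KeyError:
            raise KeyError(f"no prescription level for target {structure!r}") from None

    @property
    def dose_per_fraction(self) -> dict[str, float]:
        return {k: v / self.n_fractions for k, v in self.levels.items()}
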