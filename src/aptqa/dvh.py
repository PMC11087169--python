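"""Cumulative DVHs and the five dose-volume endpoints.

The endpoints are the ones used for head-and-neck plan evaluation:

* ``V100`` — percentage of a target's volume receiving at least 100% of
  its prescription dose (inclusive comparison).
* ``D98`` — minimal dose received by the best-covered 98% of a
  structure, reported as % of prescription for targets.
* ``Dmax`` — maximum voxel dose within the structure, as % of
  prescription (reported for CTV-High).
* ``Dmean`` — mean structure dose in Gy-RBE.
* ``D0.03cc`` — minimal dose within the hottest 0.03 cm^3 of the
  structure (near-maximum surrogate for serial organs), in Gy-RBE.

All metrics are computed bin-free from the sorted voxel doses; the
binned cumulative DVH curve exists for display and cross-checking only.
Volume percentages are always relative to the structure's own volume,
and percent doses relative to that target's own prescription level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grids import DoseGrid, Prescription, StructureMask, require_congruent

__all__ = [
    "DVHCurve",
    "cumulative_dvh",
    "volume_at_dose",
    "dose_at_volume",
    "dose_at_cc",
    "extract_endpoints",
    "ENDPOINT_COLUMNS",
]

#: Column order of the endpoint table dialect.
ENDPOINT_COLUMNS = ["V100", "D98", "Dmax", "Dmean", "D0.03cc"]

DEFAULT_BIN_WIDTH = 0.01  # Gy-RBE


@dataclass(frozen=True)
class DVHCurve:
    """A cumulative dose-volume histogram.

    ``volume_pct[i]`` is the percentage of the structure volume
    receiving at least ``dose[i]`` Gy-RBE.  The curve starts at 100% at
    zero dose and is non-increasing.
    """

    dose: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        vol = np.asarray(self.volume_pct, dtype=float)
        if dose.shape != vol.shape or dose.ndim != 1:
            raise ValueError("dose and volume_pct must be 1-D arrays of equal length")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "volume_pct", vol)

    def volume_at(self, dose: float) -> float:
        """Relative volume (%) at a dose threshold, by step lookup."""
        idx = np.searchsorted(self.dose, dose, side="right") - 1
        if idx < 0:
            return 100.0
        return float(self.volume_pct[idx])


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    require_congruent(dose, mask)
    return dose.values[mask.mask]


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVHCurve:
    """Cumulative DVH of ``mask`` on ``dose``, normalised to the
    structure's own volume.

    Bin edges run from zero to just past the structure maximum in steps
    of ``bin_width`` (Gy-RBE).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.sort(_structure_doses(dose, mask))
    n = d.size
    edges = np.arange(0.0, d[-1] + 2 * bin_width, bin_width)
    # volume receiving >= edge, by binary search on the sorted doses
    at_least = n - np.searchsorted(d, edges, side="left")
    return DVHCurve(edges, 100.0 * at_least / n)


def volume_at_dose(dose: DoseGrid, mask: StructureMask, threshold: float) -> float:
    """Percentage of the structure receiving at least ``threshold`` Gy-RBE."""
    d = _structure_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(d >= threshold)) / d.size


def dose_at_volume(dose: DoseGrid, mask: StructureMask, volume_pct: float) -> float:
    """Largest dose d such that at least ``volume_pct`` % of the
    structure receives >= d.

    Computed by linear interpolation on the cumulative volume fraction
    of the descending-sorted voxel doses: with doses ``e_1 >= ... >=
    e_n`` of equal voxel volume, the point (k/n, e_k) anchors the curve
    and queries between anchors interpolate linearly.  ``volume_pct =
    100`` returns the structure minimum dose.
    """
    if not 0 < volume_pct <= 100:
        raise ValueError(f"volume_pct must be in (0, 100], got {volume_pct}")
    e = np.sort(_structure_doses(dose, mask))[::-1]
    n = e.size
    q = np.arange(1, n + 1) / n
    return float(np.interp(volume_pct / 100.0, q, e))


def dose_at_cc(dose: DoseGrid, mask: StructureMask, cc: float) -> float:
    """Minimal dose within the hottest ``cc`` cm^3 of the structure.

    Voxel doses are sorted descending and voxel volumes accumulated;
    when the requested volume boundary falls inside a voxel, that
    voxel's dose is reported (conservative partial-voxel rule, no
    sub-voxel dose model).
    """
    e = np.sort(_structure_doses(dose, mask))[::-1]
    voxel_cc = dose.voxel_volume_cc
    total = e.size * voxel_cc
    if not 0 < cc <= total + 1e-12:
        raise ValueError(
            f"requested volume {cc} cc outside (0, structure volume {total:.4f} cc]"
        )
    cumvol = voxel_cc * np.arange(1, e.size + 1)
    idx = int(np.searchsorted(cumvol, min(cc, total), side="left"))
    idx = min(idx, e.size - 1)
    return float(e[idx])


# metric applicability mirrors the endpoint tables: targets carry
# coverage metrics, OARs carry mean and near-maximum dose
_SMALL_VOLUME_CC = 0.03


def _endpoint_row(
    dose: DoseGrid, mask: StructureMask, rx: Prescription | None
) -> dict[str, float]:
    row: dict[str, float] = {c: np.nan for c in ENDPOINT_COLUMNS}
    if mask.role == "target":
        if rx is None:
            raise ValueError("targets require a prescription")
        level = rx.level_for(mask.name)
        row["V100"] = volume_at_dose(dose, mask, level)
        row["D98"] = 100.0 * dose_at_volume(dose, mask, 98.0) / level
        if mask.name == "CTV-High":
            row["Dmax"] = 100.0 * float(_structure_doses(dose, mask).max()) / level
    else:
        d = _structure_doses(dose, mask)
        row["Dmean"] = float(d.mean())
        vol = mask.volume_cc(dose)
        cc = min(_SMALL_VOLUME_CC, vol)
        row["D0.03cc"] = dose_at_cc(dose, mask, cc)
    return row


def extract_endpoints(
    dose: DoseGrid,
    structures: Iterable[StructureMask] | Mapping[str, StructureMask],
    rx: Prescription | None = None,
) -> pd.DataFrame:
    """Endpoint table for a set of structures on one dose grid.

    Returns a DataFrame indexed by structure name with the columns
    ``V100, D98, Dmax, Dmean, D0.03cc``; metrics that do not apply to a
    structure (or structures passed as empty masks) are NaN, matching
    the missing marker of the CSV dialect.
    """
    if isinstance(structures, Mapping):
        structures = structures.values()
    rows: dict[str, dict[str, float]] = {}
    for mask in structures:
        if mask.role == "target" and rx is not None and mask.name not in rx.levels:
            raise ValueError(
                f"target {mask.name!r} present but has no prescription level"
            )
        if mask.is_empty:
            rows[mask.name] = {c: np.nan for c in ENDPOINT_COLUMNS}
            continue
        rows[mask.name] = _endpoint_row(dose, mask, rx)
    return pd.DataFrame.from_dict(rows, orient="index", columns=ENDPOINT_COLUMNS)
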