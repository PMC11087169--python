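"""DICOM RT adapter: RT Dose grids and RT Structure Set contours.

Reads an RT Dose object into a :class:`~aptqa.grids.DoseGrid` and
rasterizes closed planar RT Structure Set contours onto a dose grid
frame (even-odd rule, so nested contours on one slice carve holes).
Only axis-aligned geometry (identity orientation) is supported; masks
are produced directly on the dose grid, matching the pipeline's
requirement that structures be pre-resampled to the dose frame.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath

from .grids import DoseGrid, StructureMask, TARGET_STRUCTURES

__all__ = ["read_rt_dose", "rasterize_rt_struct"]

_IDENTITY = (1, 0, 0, 0, 1, 0)


def _as_dataset(source) -> pydicom.Dataset:
    if isinstance(source, pydicom.Dataset):
        return source
    return pydicom.dcmread(str(source))


def read_rt_dose(source) -> DoseGrid:
    """Load an RT Dose object (path or pydicom Dataset).

    Pixel values are scaled by ``DoseGridScaling``; the frame offsets
    must be uniform (regular z spacing).  The returned array is indexed
    ``[x, y, z]`` with origin at ``ImagePositionPatient``.
    """
    ds = _as_dataset(source)
    orient = tuple(round(float(v)) for v in getattr(ds, "ImageOrientationPatient", _IDENTITY))
    if orient != _IDENTITY:
        raise ValueError(f"only identity orientation supported, got {orient}")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols) = (z, y, x)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("irregular GridFrameOffsetVector not supported")
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    spacing = (col_spacing, row_spacing, float(dz[0]) if offsets.size > 1 else 1.0)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values.transpose(2, 1, 0), spacing, origin)


def _slice_index(z: float, grid: DoseGrid) -> int | None:
    k = (z - grid.origin[2]) / grid.spacing[2]
    idx = int(round(k))
    if abs(k - idx) > 0.5 or not 0 <= idx < grid.shape[2]:
        return None
    return idx


def rasterize_rt_struct(
    source,
    frame: DoseGrid,
    names: Iterable[str] | None = None,
    roles: Mapping[str, str] | None = None,
) -> dict[str, StructureMask]:
    """Rasterize RT Structure Set contours onto a dose-grid frame.

    Each closed planar contour is filled at the voxel centers of its
    nearest slice; multiple contours on one slice combine by XOR
    (even-odd rule).  ``names`` restricts the ROIs; ``roles`` overrides
    the target/OAR classification otherwise inferred from the canonical
    CTV names.
    """
    ds = _as_dataset(source)
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    wanted = set(names) if names is not None else None
    xs, ys, _ = frame.axes()
    grid_pts = np.column_stack([m.ravel() for m in np.meshgrid(xs, ys, indexing="ij")])
    out: dict[str, StructureMask] = {}
    for roi_contour in ds.ROIContourSequence:
        name = roi_names[int(roi_contour.ReferencedROINumber)]
        if wanted is not None and name not in wanted:
            continue
        mask = np.zeros(frame.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            idx = _slice_index(float(pts[:, 2].mean()), frame)
            if idx is None:
                continue
            inside = MplPath(pts[:, :2]).contains_points(grid_pts)
            mask[:, :, idx] ^= inside.reshape(frame.shape[0], frame.shape[1])
        role = (roles or {}).get(name, "target" if name in TARGET_STRUCTURES else "oar")
        out[name] = StructureMask(name, mask, role=role)
    return out
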