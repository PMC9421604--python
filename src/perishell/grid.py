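"""Voxel-grid container shared by every stage of the pipeline.

A :class:`VolumeGrid` couples a 3-D array with its physical voxel spacing
(mm per voxel, per axis) and, when relevant, the index of the midsagittal
plane used for contralateral mirroring.  Axis convention throughout the
package: axis 0 runs left-right (the sagittal index), axis 1 runs
posterior-to-anterior (anterior-positive), axis 2 inferior-to-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "from_nifti", "to_nifti"]


@dataclass
class VolumeGrid:
    """A 3-D scalar or binary field with physical spacing.

    Parameters
    ----------
    values : ndarray
        3-D array.  Binary masks may be bool or {0, 1} numeric.
    spacing : tuple of float
        mm per voxel along each axis; strictly positive.
    midline_index : float, optional
        Position of the midsagittal mirror plane along axis 0.  May be
        half-integer (even-sized grids mirror about a voxel boundary).
    axis_order : str
        Free-form anatomical orientation tag; default ``"LAS"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    midline_index: float | None = None
    axis_order: str = "LAS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    # -- basic queries -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def is_binary(self) -> bool:
        v = self.values
        if v.dtype == bool:
            return True
        return bool(np.isin(v, (0, 1)).all())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        """Number of set voxels (binary grids)."""
        return int(np.count_nonzero(self.values))

    def require_binary(self, name: str = "mask") -> np.ndarray:
        if not self.is_binary:
            raise ValueError(f"{name} must be binary (values in {{0,1}})")
        return self.values.astype(bool)

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry and different data."""
        return replace(self, values=values)

    def astype_binary(self) -> "VolumeGrid":
        return self.with_values(self.require_binary())


def from_nifti(path: str | Path, midline_index: float | None = None) -> VolumeGrid:
    """Load a NIfTI-1 volume; spacing is read from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(values=data, spacing=spacing, midline_index=midline_index)


def to_nifti(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a grid as NIfTI-1 with a diagonal affine built from the spacing."""
    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    data = grid.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # surface the offending path per the I/O contract
        raise OSError(f"failed writing volume to {path}: {exc}") from exc
    return path
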