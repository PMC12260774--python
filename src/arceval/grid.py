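"""Voxel-grid containers shared by the dose and robustness modules.

Arrays are indexed (x, y, z); ``origin`` and ``spacing`` are in mm.
NRRD / MetaImage I/O goes through SimpleITK (whose arrays are (z, y, x);
transposed on the way in and out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "DoseGrid",
    "RoiMask",
    "DeformationField",
    "GeometryError",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
]


class GeometryError(ValueError):
    pass


def _as_triple(x) -> Tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class _Grid:
    values: np.ndarray
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.origin = _as_triple(self.origin)
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be > 0, got {self.spacing}")

    @property
    def shape(self):
        return self.values.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_geometry(self, other: "_Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def require_same_geometry(self, other: "_Grid", what: str = "grids") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} have mismatched geometry: "
                f"{self.shape}/{self.origin}/{self.spacing} vs "
                f"{other.shape}/{other.origin}/{other.spacing}"
            )


@dataclass
class DoseGrid(_Grid):
    """Scalar dose in Gy on a regular voxel grid."""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(f"dose grid must be 3-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("dose grid contains non-finite values")
        if np.any(self.values < 0):
            raise GeometryError("dose grid contains negative values")


@dataclass
class RoiMask(_Grid):
    """Boolean region-of-interest mask sharing a DoseGrid geometry."""

    name: str = ""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got shape {self.values.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_cm3


@dataclass
class DeformationField(_Grid):
    """Per-voxel displacement vectors (mm), shape (nx, ny, nz, 3), on the
    planning geometry; maps planning coordinates into the repeat-anatomy
    frame for dose pull-back."""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[3] != 3:
            raise GeometryError(
                f"deformation field must have shape (nx, ny, nz, 3), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("deformation field contains non-finite values")


# ---------------------------------------------------------------------------
# SimpleITK-backed I/O (NRRD / MetaImage by file extension)


def _to_sitk(values: np.ndarray, origin, spacing, vector: bool = False):
    import SimpleITK as sitk

    arr = np.moveaxis(values, (0, 1, 2), (2, 1, 0))  # (x,y,z[,c]) -> (z,y,x[,c])
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=vector)
    img.SetOrigin(tuple(float(o) for o in origin))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img):
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(img)  # (z,y,x[,c])
    values = np.moveaxis(arr, (2, 1, 0), (0, 1, 2))
    return values, tuple(img.GetOrigin()), tuple(img.GetSpacing())


def write_grid(grid: DoseGrid, path) -> None:
    import SimpleITK as sitk

    sitk.WriteImage(_to_sitk(grid.values, grid.origin, grid.spacing), str(path))


def read_grid(path) -> DoseGrid:
    import SimpleITK as sitk

    values, origin, spacing = _from_sitk(sitk.ReadImage(str(path)))
    return DoseGrid(values=np.asarray(values, dtype=float), origin=origin, spacing=spacing)


def write_mask(mask: RoiMask, path) -> None:
    import SimpleITK as sitk

    sitk.WriteImage(
        _to_sitk(mask.values.astype(np.uint8), mask.origin, mask.spacing), str(path)
    )


def read_mask(path, name: str = "") -> RoiMask:
    import SimpleITK as sitk

    values, origin, spacing = _from_sitk(sitk.ReadImage(str(path)))
    return RoiMask(values=values > 0, origin=origin, spacing=spacing, name=name)


def write_field(fieldgrid: DeformationField, path) -> None:
    import SimpleITK as sitk

    sitk.WriteImage(
        _to_sitk(fieldgrid.values, fieldgrid.origin, fieldgrid.spacing, vector=True), str(path)
    )


def read_field(path) -> DeformationField:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values, origin, spacing = _from_sitk(img)
    return DeformationField(values=values, origin=origin, spacing=spacing)
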