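"""Volumetric containers and NIfTI round-tripping.

All volumes in the package live on a common regular grid: a 3-D scalar array
plus voxel spacing (mm) and a grid origin (mm).  Array axes follow the
convention (anterior->posterior, right->left, inferior->superior), so axis 2
is the cranial-caudal axis along which the breathing motion acts and axes
0/1 span the axial plane in which the treatment beams lie.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

from .errors import GeometryError

Spacing = tuple[float, float, float]


@dataclass
class Volume:
    """A scalar field on a regular 3-D grid."""

    values: np.ndarray
    spacing: Spacing = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing_cm(self) -> tuple[float, float, float]:
        return tuple(s / 10.0 for s in self.spacing)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise GeometryError(
                f"grid mismatch: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )

    def with_values(self, values: np.ndarray) -> "Volume":
        """Same grid, new payload (preserves the concrete subclass)."""
        return replace(self, values=np.asarray(values))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class HUVolume(Volume):
    """CT numbers in Hounsfield units (water = 0, air ~ -1000)."""

    def __post_init__(self):
        super().__post_init__()
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("HU volume contains non-finite values")


@dataclass
class RSPVolume(Volume):
    """Relative proton stopping power (water = 1)."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.values < 0):
            raise GeometryError("stopping power must be nonnegative")


@dataclass
class DoseVolume(Volume):
    """Dose in percent of the prescription."""


def _affine(vol: Volume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def save_nifti(vol: Volume, path, dtype=None) -> None:
    data = vol.values
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == np.bool_:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(vol)), str(path))


def load_nifti(path, cls=Volume) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return cls(np.asanyarray(img.dataobj).astype(np.float64), spacing, origin)


def load_mask(path) -> tuple[np.ndarray, Spacing]:
    vol = load_nifti(path)
    return vol.values > 0.5, vol.spacing
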