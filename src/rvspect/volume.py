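"""3D scalar fields on a regular grid, with NIfTI round-trip.

A :class:`VolumeGrid` is the common container for activity maps (MBq/mL),
CT-like volumes (HU), density maps (g/cm^3) and attenuation maps (cm^-1).
Arrays are indexed ``[x, y, z]``; ``voxel_size`` is in mm and ``origin`` is
the world coordinate (mm) of the center of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_volume", "save_volume"]


@dataclass
class VolumeGrid:
    """3D scalar field with voxel size and origin.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``.
    voxel_size
        Voxel edge lengths in mm, ``(dx, dy, dz)``.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mL = 1000 mm^3)."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    def total_activity(self) -> float:
        """Sum of ``concentration * voxel volume``; MBq if data is MBq/mL."""
        return float(self.data.sum()) * self.voxel_volume_ml

    def same_grid_as(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self, data: np.ndarray | None = None) -> "VolumeGrid":
        """A new grid with the same geometry and (optionally) new data."""
        return VolumeGrid(
            data=self.data.copy() if data is None else np.asarray(data),
            voxel_size=self.voxel_size,
            origin=self.origin,
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff


def save_volume(vol: VolumeGrid, path: str) -> None:
    """Write a volume as NIfTI; the affine carries voxel size and origin."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine())
    nib.save(img, path)


def load_volume(path: str, dtype=None) -> VolumeGrid:
    """Read a NIfTI volume written by :func:`save_volume`."""
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if dtype is not None:
        data = data.astype(dtype)
    aff = img.affine
    voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    return VolumeGrid(data=data, voxel_size=voxel_size, origin=origin)
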