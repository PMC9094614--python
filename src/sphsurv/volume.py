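"""Voxel volume container with physical geometry, plus NIfTI I/O.

Coordinate convention: voxel index (i, j, k) has its physical center at
``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing`` (in mm).  All geometric
operations in the package work in physical millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """3-D scalar grid with physical spacing (mm/voxel) and origin (mm)."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive componentwise")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx + 0.5) * self.spacing

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates (..., 3) to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) / self.spacing - 0.5

    def same_geometry(self, other: "VoxelVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    # -- NIfTI round trip ---------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin + 0.5 * self.spacing
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelVolume":
        img = nib.load(str(path))
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        affine = np.asarray(img.affine)
        origin = affine[:3, 3] - 0.5 * spacing
        return cls(
            values=np.asarray(img.dataobj, dtype=np.float64),
            spacing=spacing,
            origin=origin,
        )
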