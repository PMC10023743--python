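"""Voxel-grid container shared by all masks and images.

A :class:`VoxelGrid` is a 3D scalar or boolean array together with its
physical-space metadata (spacing and origin in millimetres).  The axis
convention is fixed throughout the package: ``data`` is indexed ``(x, y, z)``
with ``z`` the slice (through-plane) axis.  Anisotropy is the norm for chest
CT — slice thickness of ~3 mm against in-plane pixels of ~0.5 mm — so every
geometric computation must go through ``spacing`` rather than voxel counts.

Coordinates are voxel-center based and 0-indexed: the physical position of
voxel ``(i, j, k)`` is ``origin + (i*dx, j*dy, k*dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """A 3D volume with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar image or binary mask.  Binary masks must contain only {0, 1}
        (bool arrays are accepted and kept as bool).
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel spacing in mm; ``dz`` is the slice spacing
        along the through-plane axis and may differ from ``dx, dy``.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError(
                f"VoxelGrid requires a non-empty 3D array, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3 (dx*dy*dz)."""
        return float(np.prod(self.spacing))

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm^2 (dx*dy)."""
        return float(self.spacing[0] * self.spacing[1])

    @property
    def slice_thickness(self) -> float:
        """Through-plane spacing dz in mm."""
        return float(self.spacing[2])

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (N, 3) to physical positions in mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    # -- mask helpers -------------------------------------------------------

    @property
    def is_binary(self) -> bool:
        if self.data.dtype == bool:
            return True
        vals = np.unique(self.data)
        return bool(np.isin(vals, (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        """Return the data as a boolean mask, validating binarity."""
        if self.data.dtype == bool:
            return self.data
        if not self.is_binary:
            raise ValueError("mask is not binary: values outside {0, 1} present")
        return self.data.astype(bool)

    def mask_volume_ml(self) -> float:
        """Physical volume of the nonzero voxels, in mL."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume / 1000.0

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry with different voxel data."""
        return replace(self, data=data)

    def same_grid_as(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )
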