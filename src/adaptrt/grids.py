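"""Voxel grids in world coordinates.

All geometry lives in world millimetres, LPS orientation (x: right->left,
y: anterior->posterior, z: inferior->superior).  Arrays are indexed
``values[i, j, k]`` with axis 0 = x, 1 = y, 2 = z; voxel ``(i, j, k)`` has its
center at ``origin + (i, j, k) * spacing``.  Voxel membership everywhere in
the package is decided by the voxel *center*.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class VoxelGrid:
    """A scalar field (HU, relative stopping power, dose or label) on a
    regular axis-aligned grid.

    Parameters
    ----------
    origin : (3,) float
        World coordinates (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) float
        Voxel size in mm, strictly positive.
    values : ndarray, shape (nx, ny, nz)
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3-D array")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centers, C-order."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def mask_centers(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates of the voxel centers selected by a boolean mask."""
        idx = np.argwhere(mask)
        return self.origin + idx * self.spacing

    def world_to_continuous_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def sample(self, points: np.ndarray, order: int = 1, cval: float = 0.0,
               mode: str = "constant") -> np.ndarray:
        """Interpolate the field at world points (trilinear by default)."""
        ci = self.world_to_continuous_index(points)
        return map_coordinates(self.values.astype(float), ci.T, order=order,
                               mode=mode, cval=cval)

    # -- constructors -------------------------------------------------------
    def like(self, values: np.ndarray) -> "VoxelGrid":
        if values.shape != self.shape:
            raise ValueError("shape mismatch")
        return VoxelGrid(self.origin.copy(), self.spacing.copy(), values)

    def zeros_like(self, dtype=float) -> "VoxelGrid":
        return self.like(np.zeros(self.shape, dtype=dtype))

    @staticmethod
    def from_extent(lo, hi, spacing) -> "VoxelGrid":
        """Grid of zeros whose voxel centers span [lo, hi] at the given spacing."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        spacing = np.broadcast_to(np.asarray(spacing, float), (3,)).copy()
        shape = np.maximum(np.floor((hi - lo) / spacing).astype(int) + 1, 1)
        return VoxelGrid(lo, spacing, np.zeros(tuple(shape)))

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.spacing, other.spacing, atol=atol))
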