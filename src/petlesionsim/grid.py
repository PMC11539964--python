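"""Voxel grids: the common coordinate frame for images, phantoms and mu-maps.

World coordinates are in millimetres; indices are 0-based and refer to voxel
centres.  The first array axis is the left-right (x) axis, so ``arr[i, j]``
sits at world position ``origin + (i*dx, j*dy)``.  By default the grid is
centred on the world origin, which makes the midsagittal mirror plane
``x = 0`` fall exactly between (even grids) or on (odd grids) voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]

_MIN_VOXELS = 8


@dataclass(frozen=True)
class VoxelGrid:
    """A rectilinear voxel grid in world (mm) coordinates.

    Parameters
    ----------
    shape
        Voxel counts per axis, ``(nx, ny)`` or ``(nx, ny, nz)``.
    voxel_size_mm
        Voxel edge length per axis, mm.
    origin_mm
        World coordinate of the centre of voxel ``(0, 0[, 0])``.  ``None``
        (default) centres the grid on the world origin.
    """

    shape: tuple[int, ...]
    voxel_size_mm: tuple[float, ...]
    origin_mm: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        size = tuple(float(s) for s in self.voxel_size_mm)
        if len(shape) not in (2, 3):
            raise ValueError("grid must be 2-D or 3-D")
        if len(size) != len(shape):
            raise ValueError("voxel_size_mm must match shape dimensionality")
        if any(n < _MIN_VOXELS for n in shape[:2]):
            raise ValueError(f"in-plane voxel counts must be >= {_MIN_VOXELS}")
        if len(shape) == 3 and shape[2] < 1:
            raise ValueError("nz must be >= 1")
        if any(s <= 0 for s in size):
            raise ValueError("voxel sizes must be positive")
        if self.origin_mm is None:
            origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, size))
        else:
            origin = tuple(float(o) for o in self.origin_mm)
            if len(origin) != len(shape):
                raise ValueError("origin_mm must match shape dimensionality")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", size)
        object.__setattr__(self, "origin_mm", origin)

    # ------------------------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def fov_mm(self) -> tuple[float, ...]:
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_mm))

    @property
    def voxel_volume(self) -> float:
        """Voxel area (mm^2) in 2-D, volume (mm^3) in 3-D."""
        return float(np.prod(self.voxel_size_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along ``axis``."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm[axis] * np.arange(n)

    def coord_grids(self) -> tuple[np.ndarray, ...]:
        """Broadcastable world-coordinate arrays, one per axis."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(self.ndim)),
                           indexing="ij", sparse=True)

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.voxel_size_mm)

    def world_to_index(self, world) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def contains_world(self, world) -> bool:
        idx = self.world_to_index(world)
        return bool(np.all(idx >= -0.5) and
                    np.all(idx <= np.asarray(self.shape) - 0.5))

    def mirror_x_world(self, x_mm: float) -> float:
        """Reflect an x coordinate about the grid's midsagittal plane."""
        mid_index = (self.shape[0] - 1) / 2.0
        mid_world = self.origin_mm[0] + mid_index * self.voxel_size_mm[0]
        return 2.0 * mid_world - x_mm

    def validate_volume(self, vol: np.ndarray, name: str = "volume") -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape != self.shape:
            raise ValueError(f"{name} shape {vol.shape} != grid shape {self.shape}")
        return vol
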