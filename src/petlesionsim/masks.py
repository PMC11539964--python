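"""Spherical/disc voxel membership — the one rule shared by lesion
rasterization and VOI definition: a voxel belongs to the region iff its
centre lies within ``diameter/2`` of the region centre (Euclidean, mm)."""

from __future__ import annotations

import numpy as np

from .grid import VoxelGrid

__all__ = ["sphere_mask"]


def sphere_mask(grid: VoxelGrid, center_mm, diameter_mm: float) -> np.ndarray:
    """Boolean volume of voxels whose centres fall inside the sphere/disc.

    In 2-D the "sphere" is a disc; in 3-D it is a true sphere.  ``center_mm``
    may carry a trailing z coordinate that is ignored on 2-D grids.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    center = np.asarray(center_mm, dtype=float)[: grid.ndim]
    if center.size != grid.ndim:
        raise ValueError("center_mm dimensionality below grid dimensionality")
    coords = grid.coord_grids()
    r2 = sum((c - c0) ** 2 for c, c0 in zip(coords, center))
    return np.asarray(r2 <= (diameter_mm / 2.0) ** 2)
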