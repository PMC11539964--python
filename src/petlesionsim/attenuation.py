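"""511 keV attenuation maps (mu-maps) from CT numbers or tissue labels.

Two routes are modelled:

* **CTAC** — the ground truth: the standard bilinear CT-number conversion,
  mu = mu_water * (1 + HU/1000) for HU <= 0 and mu = mu_water + HU * slope
  above water, with the break at 0 HU.
* **Dixon-style MRAC** — fixed per-class coefficients from a water/fat
  segmentation that cannot see bone: bone voxels receive the soft-tissue
  coefficient, which is exactly the under-correction this package exists to
  quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .phantom import AIR, BONE, FAT, SOFT, TissueLabelVolume

__all__ = ["MuMap", "hu_to_mu_ctac", "derive_mrac_dixon",
           "MU_WATER_PER_CM", "BONE_SLOPE_PER_HU", "DEFAULT_DIXON_MU"]

#: linear attenuation coefficient of water at 511 keV, 1/cm
MU_WATER_PER_CM = 0.0975
#: bilinear slope above 0 HU, 1/cm per HU
BONE_SLOPE_PER_HU = 5.64e-5


def _bilinear(hu: float) -> float:
    if hu <= 0:
        return MU_WATER_PER_CM * (1.0 + hu / 1000.0)
    return MU_WATER_PER_CM + hu * BONE_SLOPE_PER_HU


#: fixed Dixon segmentation coefficients, 1/cm.  Fat and soft tissue carry
#: the 511 keV conversion of their nominal CT numbers (-90 / +40 HU), so the
#: MRAC map agrees with CTAC everywhere except bone; bone voxels receive the
#: soft-tissue coefficient ("without bones") — the under-correction under
#: study.  The classic water value 0.0975 remains available via the
#: ``coefficients`` argument.
DEFAULT_DIXON_MU = {AIR: 0.0, FAT: _bilinear(-90.0), SOFT: _bilinear(40.0),
                    BONE: _bilinear(40.0)}


@dataclass(frozen=True)
class MuMap:
    """Linear attenuation coefficients at 511 keV (1/cm) on an image grid."""

    grid: VoxelGrid
    mu_per_cm: np.ndarray
    method: str = "custom"  # CTAC | MRAC_dixon | custom

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_per_cm, dtype=float)
        self.grid.validate_volume(mu, "mu_per_cm")
        if not np.all(np.isfinite(mu)):
            raise ValueError("mu must be finite")
        if np.any(mu < 0):
            raise ValueError("mu must be non-negative")
        object.__setattr__(self, "mu_per_cm", mu)


def hu_to_mu_ctac(hu: np.ndarray, grid: VoxelGrid,
                  mu_water: float = MU_WATER_PER_CM,
                  slope_bone: float = BONE_SLOPE_PER_HU) -> MuMap:
    """Bilinear CT-number to 511 keV mu conversion (the CTAC route).

    HU <= 0: ``mu_water * (1 + HU/1000)``; HU > 0: ``mu_water + HU*slope``.
    Results below zero (HU < -1000) clamp to zero.
    """
    hu = grid.validate_volume(np.asarray(hu, dtype=float), "hu")
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU volume must be finite")
    mu = np.where(hu <= 0,
                  mu_water * (1.0 + hu / 1000.0),
                  mu_water + hu * slope_bone)
    return MuMap(grid, np.maximum(mu, 0.0), method="CTAC")


def derive_mrac_dixon(labels: TissueLabelVolume,
                      coefficients: dict[int, float] | None = None) -> MuMap:
    """Bone-free Dixon-style MRAC: fixed mu per segmented tissue class."""
    coeff = dict(DEFAULT_DIXON_MU if coefficients is None else coefficients)
    lab = labels.labels
    codes = np.unique(lab)
    unknown = set(codes.tolist()) - set(coeff)
    if unknown:
        raise ValueError(f"unknown label codes {sorted(unknown)}")
    mu = np.zeros(lab.shape, dtype=float)
    for code in codes:
        mu[lab == code] = coeff[int(code)]
    return MuMap(labels.grid, mu, method="MRAC_dixon")
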