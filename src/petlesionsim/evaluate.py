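"""SUV quantitation and error statistics.

Covers SUV conversion, VOI statistics, the SUV Error Ratio (MRAC/CTAC mean
SUV within a VOI), the Lesion Error Ratio (original pair ratio divided by
the matched synthetic pair ratio; unity means the synthetic lesion behaves
like the original under both AC methods), voxel-wise SUV difference
percentages with their mean/SD/RMSE/max summaries, Bland-Altman limits of
agreement and an ordinary least-squares trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .grid import VoxelGrid
from .masks import sphere_mask
from .phantom import BONE, TissueLabelVolume

__all__ = [
    "ScanMeta", "VOIStats", "RatioRecord", "DiffStats", "BlandAltmanResult",
    "to_suv", "voi_mask", "voi_stats", "suv_error_ratio", "lesion_error_ratio",
    "voxel_diff_percent", "diff_stats", "bland_altman", "linear_trend",
    "voi_bone_fraction",
]

DEFAULT_CTAC_SUV_FLOOR = 1e-6


class DegenerateVOIError(ValueError):
    """A VOI with no usable voxels (empty mask or zero reference uptake)."""


@dataclass(frozen=True)
class ScanMeta:
    """Injected dose (decay-corrected to scan start) and patient weight."""

    injected_dose_mbq: float = 370.0
    patient_weight_kg: float = 74.0

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0 or self.patient_weight_kg <= 0:
            raise ValueError("dose and weight must be strictly positive")

    @property
    def suv_one_kbq_ml(self) -> float:
        """Activity concentration (kBq/mL) corresponding to SUV = 1."""
        return self.injected_dose_mbq * 1000.0 / (self.patient_weight_kg * 1000.0)


@dataclass(frozen=True)
class VOIStats:
    mean_suv: float
    max_suv: float
    n_voxels: int
    bone_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise DegenerateVOIError("VOI must contain at least one voxel")
        if self.max_suv < self.mean_suv - 1e-9:
            raise ValueError("max_suv must be >= mean_suv")


@dataclass(frozen=True)
class RatioRecord:
    """Per matched pair: both SUV Error Ratios and their quotient."""

    pair_id: str
    diameter_mm: float
    suv_error_ratio_original: float
    suv_error_ratio_synthetic: float
    lesion_error_ratio: float


@dataclass(frozen=True)
class DiffStats:
    """Summary of voxel-wise SUV difference percentages within one VOI."""

    mu_pct: float
    sigma_pct: float
    rmse_pct: float
    max_abs_pct: float
    diff_max_signed_pct: float
    n_voxels: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if abs(self.rmse_pct - float(np.hypot(self.mu_pct, self.sigma_pct))) > 1e-9:
            raise ValueError("RMSE must equal sqrt(mu^2 + sigma^2)")


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    loa_low: float
    loa_high: float
    n_pairs: int
    sd_difference: float
    frac_within: float


# ----------------------------------------------------------------------


def to_suv(activity_kbq_ml: np.ndarray, meta: ScanMeta) -> np.ndarray:
    """activity (kBq/mL) / (injected dose [kBq] / body weight [g])."""
    return np.asarray(activity_kbq_ml, dtype=float) / meta.suv_one_kbq_ml


def voi_mask(center_mm, diameter_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Spherical VOI mask — same membership rule as lesion rasterization."""
    mask = sphere_mask(grid, center_mm, diameter_mm)
    if not mask.any():
        raise DegenerateVOIError("VOI captures no voxel centres")
    return mask


def voi_stats(suv: np.ndarray, mask: np.ndarray,
              labels: TissueLabelVolume | None = None) -> VOIStats:
    vals = np.asarray(suv, dtype=float)[mask]
    if vals.size == 0:
        raise DegenerateVOIError("empty VOI")
    frac = voi_bone_fraction(mask, labels) if labels is not None else 0.0
    return VOIStats(mean_suv=float(vals.mean()), max_suv=float(vals.max()),
                    n_voxels=int(vals.size), bone_fraction=frac)


def suv_error_ratio(mean_mrac: float, mean_ctac: float) -> float:
    """[Mean MRAC] / [Mean CTAC] within one VOI."""
    if mean_ctac <= 0:
        raise DegenerateVOIError("CTAC mean SUV must be positive")
    return float(mean_mrac) / float(mean_ctac)


def lesion_error_ratio(ratio_original: float, ratio_synthetic: float) -> float:
    """Original pair's SUV Error Ratio divided by the synthetic pair's."""
    if ratio_synthetic <= 0:
        raise DegenerateVOIError("synthetic SUV Error Ratio must be positive")
    return float(ratio_original) / float(ratio_synthetic)


def voxel_diff_percent(suv_mrac: np.ndarray, suv_ctac: np.ndarray,
                       mask: np.ndarray,
                       ctac_floor: float = DEFAULT_CTAC_SUV_FLOOR
                       ) -> tuple[np.ndarray, int]:
    """Per-voxel 100*(SUV_MRAC - SUV_CTAC)/SUV_CTAC over the mask.

    Voxels whose CTAC SUV falls below ``ctac_floor`` are excluded; the
    number excluded is returned alongside the differences.
    """
    mrac = np.asarray(suv_mrac, dtype=float)[mask]
    ctac = np.asarray(suv_ctac, dtype=float)[mask]
    if mrac.size == 0:
        raise DegenerateVOIError("mask selects no voxels")
    ok = ctac >= ctac_floor
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise DegenerateVOIError("all VOI voxels below the CTAC SUV floor")
    diffs = 100.0 * (mrac[ok] - ctac[ok]) / ctac[ok]
    return diffs, n_excluded


def diff_stats(diffs, n_excluded: int = 0) -> DiffStats:
    """mean / SD / RMSE / max of voxel difference percentages.

    The SD uses the population divisor N (the VOI voxel set is exhaustive),
    and RMSE = sqrt(mu^2 + sigma^2).  The signed maximum is the single
    largest-magnitude discrepancy with its sign preserved.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise DegenerateVOIError("no difference values")
    mu = float(d.mean())
    sigma = float(d.std(ddof=0))
    k = int(np.abs(d).argmax())
    return DiffStats(mu_pct=mu, sigma_pct=sigma,
                     rmse_pct=float(np.hypot(mu, sigma)),
                     max_abs_pct=float(np.abs(d).max()),
                     diff_max_signed_pct=float(d[k]),
                     n_voxels=int(d.size), n_excluded=int(n_excluded))


def bland_altman(pairs) -> BlandAltmanResult:
    """Limits of agreement: mean difference +/- 1.96 * SD (sample SD, N-1)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(mean_difference=mean, loa_low=lo, loa_high=hi,
                             n_pairs=int(arr.shape[0]), sd_difference=sd,
                             frac_within=within)


def linear_trend(x, y) -> tuple[float, float]:
    """OLS slope and R^2 of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 matched points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:  # flat response: no trend by definition
        return 0.0, 0.0
    res = _scipy_stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def voi_bone_fraction(mask: np.ndarray, labels: TissueLabelVolume) -> float:
    """Fraction of masked voxels labelled bone."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise DegenerateVOIError("empty mask")
    return float((labels.labels[m] == BONE).mean())
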