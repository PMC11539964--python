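"""Synthetic pelvis-like digital phantoms.

A phantom is three co-registered volumes on one grid: integer tissue labels
(air / fat / soft tissue / bone), an activity concentration map (kBq/mL) and
a CT-number map (HU).  The anatomy is deliberately schematic — an elliptical
body with a subcutaneous fat rim, two mirrored iliac/acetabular bone analogs
and a midline sacral analog — but it reproduces the features that matter for
attenuation-correction studies in the pelvis: bilateral symmetry, and target
regions ranging from bone-dominant to purely soft tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid
from .masks import sphere_mask

__all__ = [
    "AIR", "FAT", "SOFT", "BONE",
    "TissueLabelVolume", "PhantomVolume", "TargetSite",
    "make_pelvis_phantom", "default_target_sites", "labels_to_hu",
    "DEFAULT_CLASS_HU",
]

AIR, FAT, SOFT, BONE = 0, 1, 2, 3

#: Nominal CT numbers per tissue class (HU).
DEFAULT_CLASS_HU = {AIR: -1000.0, FAT: -90.0, SOFT: 40.0, BONE: 700.0}

# texture is clipped into these per-class bands so label<->HU invariants
# (air <= -900, bone >= +200) survive any texture sigma
_CLASS_HU_BAND = {
    AIR: (-1050.0, -950.0),
    FAT: (-150.0, -30.0),
    SOFT: (0.0, 100.0),
    BONE: (250.0, 1200.0),
}


class PhantomError(ValueError):
    """Phantom construction/derivation failure (sizing, missing tissue...)."""


@dataclass(frozen=True)
class TissueLabelVolume:
    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        self.grid.validate_volume(labels, "labels")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        if labels.min() < AIR or labels.max() > BONE:
            raise ValueError("labels must be in {0 air, 1 fat, 2 soft, 3 bone}")
        border = np.ones(labels.shape, dtype=bool)
        border[(slice(1, -1),) * 2] = False  # in-plane border only
        if np.any(labels[border] != AIR):
            raise ValueError("outer border voxels must be air")
        object.__setattr__(self, "labels", labels)

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != AIR


@dataclass(frozen=True)
class PhantomVolume:
    """The simulated patient: labels + activity (kBq/mL) + CT numbers (HU)."""

    grid: VoxelGrid
    labels: TissueLabelVolume
    activity_kbq_ml: np.ndarray
    hu: np.ndarray

    def __post_init__(self) -> None:
        act = np.asarray(self.activity_kbq_ml, dtype=float)
        hu = np.asarray(self.hu, dtype=float)
        self.grid.validate_volume(act, "activity")
        self.grid.validate_volume(hu, "hu")
        if np.any(act < 0):
            raise ValueError("activity must be non-negative")
        air = self.labels.mask(AIR)
        if np.any(act[air] != 0):
            raise ValueError("activity must be zero in air")
        if np.any(hu[air] > -900):
            raise ValueError("hu(air) must be <= -900")
        if np.any(hu[self.labels.mask(BONE)] < 200):
            raise ValueError("hu(bone) must be >= +200")
        object.__setattr__(self, "activity_kbq_ml", act)
        object.__setattr__(self, "hu", hu)


@dataclass(frozen=True)
class TargetSite:
    """An anatomical target archetype, characterised by the bone content of
    the 12 mm VOI centred on it."""

    name: str
    center_mm: tuple[float, ...]
    bone_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bone_fraction <= 1.0:
            raise ValueError("bone_fraction must lie in [0, 1]")


# ----------------------------------------------------------------------
# anatomy parameters, as fractions of the body semi-axes (a: lateral,
# b: anteroposterior); posterior is negative y
_BODY_A_FRAC = 0.40          # body lateral semi-axis / lateral FOV
_BODY_B_FRAC = 0.30          # body AP semi-axis / AP FOV
_FAT_RIM_MM = 9.0
_SACRUM_CENTER = (0.0, -0.50)        # (x/a, y/b)
_SACRUM_SEMI = (0.09, 0.06)          # (x/a, y/b)
_ILIAC_CENTER = (0.55, -0.20)        # (|x|/a, y/b), mirrored left/right
_ILIAC_R_FRAC = 0.06                 # radius / a


def _ellipse_mask(x, y, cx, cy, sa, sb):
    return ((x - cx) / sa) ** 2 + ((y - cy) / sb) ** 2 <= 1.0


def make_pelvis_phantom(grid: VoxelGrid,
                        background_kbq_ml: float = 5.0,
                        seed: int = 0,
                        symmetric: bool = True) -> PhantomVolume:
    """Generate a pelvis-like phantom on ``grid``.

    ``seed`` drives a mild (±4 %) per-phantom jitter of the body and bone
    dimensions — the stand-in for inter-patient variability — and the HU
    texture.  With ``symmetric=True`` all masks are even functions of the
    lateral coordinate relative to the grid midline, so labels and activity
    are exactly invariant under left-right mirroring.  Activity is a uniform
    ``background_kbq_ml`` in every non-air voxel.
    """
    if background_kbq_ml < 0:
        raise ValueError("background_kbq_ml must be >= 0")
    rng = np.random.default_rng(seed)
    jit = lambda: 1.0 + rng.uniform(-0.04, 0.04)  # noqa: E731

    fov = grid.fov_mm
    a = _BODY_A_FRAC * fov[0] * jit()
    b = _BODY_B_FRAC * fov[1] * jit()
    # the body must keep an air border (one voxel margin on each side)
    if (a >= fov[0] / 2 - grid.voxel_size_mm[0] * 1.5
            or b >= fov[1] / 2 - grid.voxel_size_mm[1] * 1.5):
        raise PhantomError("grid too small to contain the body ellipse")

    coords = grid.coord_grids()
    mid_x = grid.mirror_x_world(0.0) / 2.0  # x position of the mirror plane
    x = coords[0] - mid_x
    y = coords[1]
    if not symmetric:
        # small lateral offsets break the mirror symmetry without changing
        # the gross anatomy
        x = x + rng.uniform(-2.0, 2.0)

    full = lambda m: np.broadcast_to(m, grid.shape)  # noqa: E731
    body = full(_ellipse_mask(x, y, 0.0, 0.0, a, b))
    inner = full(_ellipse_mask(x, y, 0.0, 0.0, a - _FAT_RIM_MM, b - _FAT_RIM_MM))

    sac_sa = _SACRUM_SEMI[0] * a * jit()
    sac_sb = _SACRUM_SEMI[1] * b * jit()
    sacrum = full(_ellipse_mask(x, y, _SACRUM_CENTER[0] * a,
                                _SACRUM_CENTER[1] * b, sac_sa, sac_sb))
    r_il = _ILIAC_R_FRAC * a * jit()
    cx_il, cy_il = _ILIAC_CENTER[0] * a, _ILIAC_CENTER[1] * b
    iliac = full(_ellipse_mask(x, y, cx_il, cy_il, r_il, r_il)
                 | _ellipse_mask(x, y, -cx_il, cy_il, r_il, r_il))

    labels = np.full(grid.shape, AIR, dtype=np.int16)
    labels[body & ~inner] = FAT
    labels[inner] = SOFT
    labels[(sacrum | iliac) & inner] = BONE

    label_vol = TissueLabelVolume(grid, labels)
    activity = np.where(labels != AIR, float(background_kbq_ml), 0.0)
    hu = labels_to_hu(label_vol, seed=seed, texture_sigma_hu=0.0)
    phantom = PhantomVolume(grid, label_vol, activity, hu)
    # cache the realised anatomy for site derivation
    object.__setattr__(phantom, "_anatomy", {
        "a": a, "b": b, "mid_x": mid_x,
        "sacrum": (_SACRUM_CENTER[0] * a, _SACRUM_CENTER[1] * b, sac_sa, sac_sb),
        "iliac": (cx_il, cy_il, r_il),
    })
    return phantom


def default_target_sites(phantom: PhantomVolume,
                         voi_diameter_mm: float = 12.0) -> list[TargetSite]:
    """The four anatomical target archetypes of the pelvis.

    The acetabular site sits mostly inside the right iliac/acetabular bone
    (bone-dominant VOI); the sacral site straddles the left edge of the
    sacral bone (intermediate fraction, placed by a deterministic scan of
    the discretized labels); the sidewall lymph-node and posterior-bladder
    sites lie in soft tissue with essentially no bone in the VOI.  Bone
    fractions are measured on the actual label volume.
    """
    labels = phantom.labels
    if not np.any(labels.mask(BONE)):
        raise PhantomError("phantom contains no bone; cannot derive target sites")
    anat = getattr(phantom, "_anatomy", None)
    if anat is None:
        raise PhantomError("phantom lacks anatomy metadata (not generated here)")
    a, b, mid_x = anat["a"], anat["b"], anat["mid_x"]
    scx, scy, ssa, _ssb = anat["sacrum"]
    icx, icy, ir = anat["iliac"]

    body = labels.body_mask
    bone = labels.mask(BONE)

    def _frac(center):
        center = tuple(center) + ((0.0,) if phantom.grid.ndim == 3 else ())
        voi = sphere_mask(phantom.grid, center, voi_diameter_mm)
        if not voi.any() or not body[voi].all():
            return None
        return float(bone[voi].mean())

    # sacrum: deterministic scan across the left bone edge for an
    # intermediate bone fraction (the site straddles cortex and soft tissue)
    edge_x = mid_x + scx - ssa
    sacrum_center, sacrum_frac = None, None
    for off in np.arange(-4.0, 4.5, 0.5):  # +off moves into the bone
        c = (edge_x + off, scy)
        f = _frac(c)
        if f is None or not 0.0 < f < 0.75:
            continue
        if sacrum_frac is None or abs(f - 0.25) < abs(sacrum_frac - 0.25):
            sacrum_center, sacrum_frac = c, f
    if sacrum_center is None:
        raise PhantomError("could not place the sacral target site")

    centers = {
        # VOI mostly inside the right acetabular bone (bone-dominant)
        "acetabulum": (mid_x + icx - 0.35 * ir, icy),
        "sacrum": sacrum_center,
        "lymph_node": (mid_x - 0.40 * a, 0.45 * b),
        "bladder_posterior": (mid_x + 0.0, 0.0 * b),
    }
    sites = []
    for name, center in centers.items():
        center = tuple(center) + ((0.0,) if phantom.grid.ndim == 3 else ())
        voi = sphere_mask(phantom.grid, center, voi_diameter_mm)
        if not voi.any() or not body[voi].all():
            raise PhantomError(f"target site {name!r} falls outside the body")
        frac = float(labels.mask(BONE)[voi].mean())
        sites.append(TargetSite(name, center, frac))
    by = {s.name: s.bone_fraction for s in sites}
    if not (by["acetabulum"] > by["sacrum"] > max(by["lymph_node"],
                                                  by["bladder_posterior"])):
        raise PhantomError("bone-fraction ordering violated for this anatomy")
    return sites


def labels_to_hu(labels: TissueLabelVolume,
                 seed: int = 0,
                 texture_sigma_hu: float = 0.0,
                 class_hu: dict[int, float] | None = None) -> np.ndarray:
    """Map tissue labels to CT numbers, optionally with Gaussian texture.

    Texture is clipped per class so the air/bone HU invariants hold for any
    sigma.  Deterministic for a fixed seed.
    """
    class_hu = dict(DEFAULT_CLASS_HU if class_hu is None else class_hu)
    hu = np.empty(labels.labels.shape, dtype=float)
    for code, value in class_hu.items():
        hu[labels.labels == code] = value
    if texture_sigma_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, texture_sigma_hu, size=hu.shape)
        for code, (lo, hi) in _CLASS_HU_BAND.items():
            m = labels.labels == code
            hu[m] = np.clip(hu[m], lo, hi)
    return hu
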