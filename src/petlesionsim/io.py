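"""File interfaces: NIfTI volumes, lesion CSV lists, JSON sidecars and
sinogram containers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .insertion import LesionSpec
from .projection import Sinogram, SystemGeometry

__all__ = [
    "save_volume_nifti", "load_volume_nifti",
    "save_lesions_csv", "load_lesions_csv",
    "write_json", "save_sinogram", "load_sinogram",
]

_LESION_COLUMNS = ["id", "x_mm", "y_mm", "z_mm", "diameter_mm",
                   "activity_kbq_ml"]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(grid.ndim):
        aff[a, a] = grid.voxel_size_mm[a]
        aff[a, 3] = grid.origin_mm[a]
    return aff


def save_volume_nifti(path, volume: np.ndarray, grid: VoxelGrid,
                      integer: bool = False) -> None:
    """Write a (2-D or 3-D) volume as NIfTI with voxel size in the header."""
    vol = grid.validate_volume(np.asarray(volume))
    if vol.ndim == 2:
        vol = vol[:, :, None]
    dtype = np.int16 if integer else np.float32
    img = nib.Nifti1Image(vol.astype(dtype), _affine(grid))
    img.header.set_zooms(tuple(grid.voxel_size_mm) + (1.0,) * (3 - grid.ndim))
    nib.save(img, str(path))


def load_volume_nifti(path, squeeze_2d: bool = True
                      ) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[: data.ndim]
    origin = tuple(float(img.affine[a, 3]) for a in range(data.ndim))
    if squeeze_2d and data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
        zooms = zooms[:2]
        origin = origin[:2]
    grid = VoxelGrid(shape=data.shape,
                     voxel_size_mm=tuple(float(z) for z in zooms),
                     origin_mm=origin)
    return np.asarray(data), grid


def save_lesions_csv(path, lesions) -> None:
    rows = []
    for les in lesions:
        c = tuple(les.center_mm) + (0.0,) * (3 - len(les.center_mm))
        rows.append({"id": les.id, "x_mm": c[0], "y_mm": c[1], "z_mm": c[2],
                     "diameter_mm": les.diameter_mm,
                     "activity_kbq_ml": les.activity_kbq_ml})
    pd.DataFrame(rows, columns=_LESION_COLUMNS).to_csv(path, index=False)


def load_lesions_csv(path, ndim: int = 2) -> list[LesionSpec]:
    df = pd.read_csv(path)
    missing = set(_LESION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lesion CSV missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        center = (float(row.x_mm), float(row.y_mm), float(row.z_mm))[:ndim]
        out.append(LesionSpec(center_mm=center,
                              diameter_mm=float(row.diameter_mm),
                              activity_kbq_ml=float(row.activity_kbq_ml),
                              id=str(row.id)))
    return out


def write_json(path, obj) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting via repr."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_sinogram(path, sino: Sinogram) -> None:
    """Portable container (.npz) with a JSON geometry sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), values=sino.values)
    write_json(path.with_suffix(".json"), {
        "kind": sino.kind, "scale": sino.scale,
        "geometry": {"n_angles": sino.geometry.n_angles,
                     "n_radial_bins": sino.geometry.n_radial_bins,
                     "radial_spacing_mm": sino.geometry.radial_spacing_mm,
                     "fov_mm": sino.geometry.fov_mm,
                     "angles_deg": list(sino.geometry.angles_deg)},
    })


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    g = meta["geometry"]
    geom = SystemGeometry(n_angles=g["n_angles"],
                          n_radial_bins=g["n_radial_bins"],
                          radial_spacing_mm=g["radial_spacing_mm"],
                          fov_mm=g["fov_mm"],
                          angles_deg=tuple(g["angles_deg"]))
    values = np.load(path.with_suffix(".npz"))["values"]
    return Sinogram(geom, values, kind=meta["kind"], scale=meta["scale"])
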