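"""Run configuration: a strict YAML schema covering every pipeline stage.

Unknown keys are rejected (a typo must fail loudly, not silently fall back
to a default), and every random operation has a seed after resolution, so a
rerun of the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    nx: int = 128
    ny: int = 128
    voxel_mm: float = 3.0
    background_kbq_ml: float = 5.0
    symmetric: bool = True
    texture_sigma_hu: float = 0.0
    n_phantoms: int = 4


class SystemConfig(_Strict):
    n_angles: int = 96
    count_scale: float | None = None
    target_total_counts: float = 5.0e5


class AttenuationConfig(_Strict):
    mu_water_per_cm: float = 0.0975
    bone_slope_per_hu: float = 5.64e-5
    dixon_mu_fat: float = 0.088725   # bilinear(-90 HU)
    dixon_mu_soft: float = 0.099756  # bilinear(+40 HU); also assigned to bone


class ReconConfig(_Strict):
    iterations: int = 2
    subsets: int = 16
    psf_fwhm_mm: float = 4.5


class InsertionConfig(_Strict):
    n_lesions_total: int = 16
    diameter_min_mm: float = 9.0
    diameter_max_mm: float = 40.0
    lesion_kbq_ml_min: float = 15.0
    lesion_kbq_ml_max: float = 50.0
    targeted_diameter_mm: float = 12.0
    targeted_kbq_ml: float = 5000.0
    noise: bool = True
    match_contrast: str = "recon"

    @model_validator(mode="after")
    def _ranges(self):
        if not 0 < self.diameter_min_mm <= self.diameter_max_mm:
            raise ValueError("invalid diameter range")
        if self.match_contrast not in ("recon", "true"):
            raise ValueError("match_contrast must be 'recon' or 'true'")
        return self


class EvaluationConfig(_Strict):
    injected_dose_mbq: float = 370.0
    patient_weight_kg: float = 74.0
    ctac_suv_floor: float = 1.0e-6


class SeedsConfig(_Strict):
    master: int = 12345


class RunConfig(_Strict):
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    system: SystemConfig = Field(default_factory=SystemConfig)
    attenuation: AttenuationConfig = Field(default_factory=AttenuationConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    insertion: InsertionConfig = Field(default_factory=InsertionConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seeds: SeedsConfig = Field(default_factory=SeedsConfig)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path=None) -> RunConfig:
    """Load a YAML run config; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
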