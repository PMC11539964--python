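"""End-to-end study recipes: the matched contralateral validation and the
targeted four-site validation, run on synthetic phantom cohorts.

Both recipes are deterministic functions of a :class:`~petlesionsim.config.
RunConfig`: phantom seeds, acquisition seeds and lesion placements all
derive from the single master seed, and the CSV/JSON outputs of two runs
with identical configs are byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attenuation import hu_to_mu_ctac
from .config import RunConfig
from .evaluate import ScanMeta, bland_altman, diff_stats, linear_trend
from .grid import VoxelGrid
from .insertion import (LesionSpec, run_matched_study, run_targeted_study)
from .io import write_json
from .masks import sphere_mask
from .phantom import SOFT, PhantomVolume, default_target_sites, make_pelvis_phantom
from .projection import (NormalizationMap, SystemGeometry,
                         calibrate_count_scale)

__all__ = ["build_cohort", "sample_original_lesions",
           "cmd_validation1", "cmd_validation2"]


def _grid(cfg: RunConfig) -> VoxelGrid:
    p = cfg.phantom
    return VoxelGrid(shape=(p.nx, p.ny), voxel_size_mm=(p.voxel_mm, p.voxel_mm))


def _meta(cfg: RunConfig) -> ScanMeta:
    return ScanMeta(injected_dose_mbq=cfg.evaluation.injected_dose_mbq,
                    patient_weight_kg=cfg.evaluation.patient_weight_kg)


def build_cohort(cfg: RunConfig, rng: np.random.Generator
                 ) -> list[PhantomVolume]:
    grid = _grid(cfg)
    return [make_pelvis_phantom(grid,
                                background_kbq_ml=cfg.phantom.background_kbq_ml,
                                seed=int(rng.integers(2 ** 31)),
                                symmetric=cfg.phantom.symmetric)
            for _ in range(cfg.phantom.n_phantoms)]


def sample_original_lesions(phantom: PhantomVolume, n: int,
                            rng: np.random.Generator,
                            diameter_range=(9.0, 40.0),
                            activity_range=(15.0, 50.0),
                            max_tries: int = 4000) -> list[LesionSpec]:
    """Place ``n`` non-overlapping lesions in left-half soft tissue.

    Left-half placement guarantees the mirrored twins (right half) cannot
    collide with any original lesion.
    """
    grid = phantom.grid
    anat = getattr(phantom, "_anatomy")
    a, b, mid = anat["a"], anat["b"], anat["mid_x"]
    specs: list[LesionSpec] = []
    tries = 0
    while len(specs) < n and tries < max_tries:
        tries += 1
        d = float(rng.uniform(*diameter_range))
        r = d / 2.0
        x = mid - float(rng.uniform(r + 4.0, 0.72 * a))
        y = float(rng.uniform(-0.45 * b, 0.55 * b))
        mask = sphere_mask(grid, (x, y), d)
        if not mask.any() or not np.all(phantom.labels.labels[mask] == SOFT):
            continue
        if any(np.hypot(x - s.center_mm[0], y - s.center_mm[1])
               < (d + s.diameter_mm) / 2.0 + 4.0 for s in specs):
            continue
        specs.append(LesionSpec(center_mm=(x, y), diameter_mm=d,
                                activity_kbq_ml=float(rng.uniform(*activity_range)),
                                id=f"orig{len(specs)}"))
    if len(specs) < n:
        raise RuntimeError(f"could only place {len(specs)}/{n} lesions")
    return specs


def _count_scale(cfg: RunConfig, phantom: PhantomVolume,
                 geom: SystemGeometry) -> float:
    if cfg.system.count_scale is not None:
        return cfg.system.count_scale
    mu = hu_to_mu_ctac(phantom.hu, phantom.grid)
    return calibrate_count_scale(phantom.activity_kbq_ml, mu,
                                 NormalizationMap.uniform(geom), geom,
                                 cfg.system.target_total_counts)


def _provenance(cfg: RunConfig, outdir: Path, seeds: dict) -> None:
    write_json(outdir / "provenance.json", {
        "package": "petlesionsim", "version": __version__,
        "config_hash": cfg.config_hash(), "config": cfg.model_dump(),
        "seeds": seeds,
    })


def cmd_validation1(cfg: RunConfig, outdir, make_plots: bool = True) -> dict:
    """Matched contralateral insertion across a symmetric phantom cohort.

    Writes one RatioRecord row per lesion pair (CSV), a JSON summary with
    the cohort Lesion Error Ratio, diameter trend and Bland-Altman limits,
    and the two figures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seeds.master)
    cohort = build_cohort(cfg, rng)
    geom = SystemGeometry.for_grid(_grid(cfg), n_angles=cfg.system.n_angles)
    meta = _meta(cfg)

    per_phantom = np.array_split(np.arange(cfg.insertion.n_lesions_total),
                                 len(cohort))
    all_records = []
    seeds_used = {}
    for k, (phantom, chunk) in enumerate(zip(cohort, per_phantom)):
        if len(chunk) == 0:
            continue
        lesions = sample_original_lesions(
            phantom, len(chunk), rng,
            diameter_range=(cfg.insertion.diameter_min_mm,
                            cfg.insertion.diameter_max_mm),
            activity_range=(cfg.insertion.lesion_kbq_ml_min,
                            cfg.insertion.lesion_kbq_ml_max))
        study_seed = int(rng.integers(2 ** 31))
        records, study = run_matched_study(
            phantom, lesions, geom, meta=meta,
            recon_iterations=cfg.recon.iterations,
            recon_subsets=cfg.recon.subsets,
            psf_fwhm_mm=cfg.recon.psf_fwhm_mm,
            count_scale=_count_scale(cfg, phantom, geom),
            seed=study_seed, noise=cfg.insertion.noise,
            match_contrast=cfg.insertion.match_contrast,
            phantom_id=f"p{k}")
        seeds_used[f"p{k}"] = study.seeds
        all_records.extend(records)

    ratios = pd.DataFrame([asdict(r.ratios) for r in all_records])
    ratios.to_csv(outdir / "lesion_error_ratios.csv", index=False,
                  float_format="%.6f")

    ler = ratios["lesion_error_ratio"].to_numpy()
    slope, r2 = linear_trend(ratios["diameter_mm"].to_numpy(), ler)
    pairs = ratios[["suv_error_ratio_original",
                    "suv_error_ratio_synthetic"]].to_numpy()
    ba = bland_altman(pairs)
    summary = {
        "n_pairs": int(len(ler)),
        "lesion_error_ratio_mean": float(ler.mean()),
        "lesion_error_ratio_sd": float(ler.std(ddof=1)),
        "trend_slope_per_mm": slope,
        "trend_r_squared": r2,
        "bland_altman": {
            "mean_difference": ba.mean_difference,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "sd_difference": ba.sd_difference,
            "frac_within_limits": ba.frac_within,
        },
    }
    write_json(outdir / "summary.json", summary)
    _provenance(cfg, outdir, seeds_used)
    if make_plots:
        from .plots import bland_altman_plot, trend_plot
        bland_altman_plot(pairs, ba, outdir / "bland_altman.svg")
        trend_plot(ratios["diameter_mm"], ler, slope, r2,
                   outdir / "ler_vs_diameter.svg")
    return summary


def cmd_validation2(cfg: RunConfig, outdir, make_plots: bool = True,
                    noise: bool | None = None) -> dict:
    """Targeted insertion at the four anatomical archetypes.

    One 12 mm / 5000 kBq/mL lesion per site per phantom; per-lesion voxel
    difference statistics plus per-site statistics pooled across the cohort.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seeds.master)
    cohort = build_cohort(cfg, rng)
    geom = SystemGeometry.for_grid(_grid(cfg), n_angles=cfg.system.n_angles)
    sites = [default_target_sites(p, cfg.insertion.targeted_diameter_mm)
             for p in cohort]
    noise = cfg.insertion.noise if noise is None else noise
    study_seed = int(rng.integers(2 ** 31))
    records = run_targeted_study(
        cohort, sites, geom,
        diameter_mm=cfg.insertion.targeted_diameter_mm,
        activity_kbq_ml=cfg.insertion.targeted_kbq_ml,
        meta=_meta(cfg),
        recon_iterations=cfg.recon.iterations,
        recon_subsets=cfg.recon.subsets,
        psf_fwhm_mm=cfg.recon.psf_fwhm_mm,
        count_scale=_count_scale(cfg, cohort[0], geom),
        seed=study_seed, noise=noise)

    rows = []
    for r in records:
        rows.append({"phantom": r.phantom_id, "site": r.site.name,
                     "bone_fraction": r.site.bone_fraction,
                     "mean_suv_ctac": r.mean_suv_ctac,
                     "mean_suv_mrac": r.mean_suv_mrac,
                     **asdict(r.stats)})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "targeted_diff_stats.csv", index=False,
              float_format="%.6f")

    site_summary = {}
    for name in sorted({r.site.name for r in records}):
        pooled = np.concatenate([
            100.0 * (r.suv_mrac_voxels - r.suv_ctac_voxels) / r.suv_ctac_voxels
            for r in records if r.site.name == name])
        st = diff_stats(pooled)
        site_summary[name] = {
            "mu_pct": st.mu_pct, "sigma_pct": st.sigma_pct,
            "rmse_pct": st.rmse_pct, "max_abs_pct": st.max_abs_pct,
            "diff_max_signed_pct": st.diff_max_signed_pct,
            "n_voxels": st.n_voxels,
            "mean_bone_fraction": float(np.mean(
                [r.site.bone_fraction for r in records
                 if r.site.name == name])),
        }
    summary = {"n_lesions": len(records), "per_site": site_summary,
               "noise": bool(noise)}
    write_json(outdir / "summary.json", summary)
    _provenance(cfg, outdir, {"study": study_seed})
    if make_plots:
        from .plots import diffmax_boxplot, voi_suv_histogram
        diffmax_boxplot(
            {name: [r.stats.diff_max_signed_pct for r in records
                    if r.site.name == name]
             for name in site_summary},
            outdir / "diffmax_boxplot.svg")
        for r in records:
            if r.phantom_id == "p0":
                voi_suv_histogram(r.suv_ctac_voxels, r.suv_mrac_voxels,
                                  r.site.name,
                                  outdir / f"suv_hist_{r.site.name}.svg")
    return summary
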