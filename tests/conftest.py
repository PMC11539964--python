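"""Shared fixtures: grids, phantoms and the two (expensive) cohort studies.

The cohort fixtures are session-scoped so the end-to-end simulations run
once and are shared between the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from petlesionsim import (NormalizationMap, SystemGeometry, VoxelGrid,
                          calibrate_count_scale, default_target_sites,
                          hu_to_mu_ctac, make_pelvis_phantom,
                          run_targeted_study)
from petlesionsim.config import RunConfig
from petlesionsim.studies import build_cohort, cmd_validation1


@pytest.fixture(scope="session")
def desk_grid() -> VoxelGrid:
    """The default desk-scale reconstruction grid: 128 x 128 at 3 mm."""
    return VoxelGrid((128, 128), (3.0, 3.0))


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    """A 32 x 32 grid for oracle-level reconstruction tests."""
    return VoxelGrid((32, 32), (6.0, 6.0))


@pytest.fixture(scope="session")
def desk_geom(desk_grid) -> SystemGeometry:
    return SystemGeometry.for_grid(desk_grid, n_angles=96)


@pytest.fixture(scope="session")
def desk_phantom(desk_grid):
    return make_pelvis_phantom(desk_grid, background_kbq_ml=5.0, seed=0)


@pytest.fixture(scope="session")
def desk_count_scale(desk_phantom, desk_geom) -> float:
    mu = hu_to_mu_ctac(desk_phantom.hu, desk_phantom.grid)
    return calibrate_count_scale(desk_phantom.activity_kbq_ml, mu,
                                 NormalizationMap.uniform(desk_geom),
                                 desk_geom, 5.0e5)


@pytest.fixture(scope="session")
def matched_cohort_summary(tmp_path_factory) -> dict:
    """Default matched contralateral study: 4 phantoms, 12 pairs, noise on."""
    cfg = RunConfig()
    out = tmp_path_factory.mktemp("validation1")
    return cmd_validation1(cfg, out, make_plots=False)


@pytest.fixture(scope="session")
def targeted_records_noise_off(desk_geom, desk_count_scale):
    """Noise-free targeted study over the default 4-phantom cohort."""
    cfg = RunConfig()
    rng = np.random.default_rng(cfg.seeds.master)
    cohort = build_cohort(cfg, rng)
    sites = [default_target_sites(p) for p in cohort]
    return run_targeted_study(cohort, sites, desk_geom,
                              count_scale=desk_count_scale, seed=11,
                              noise=False)
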