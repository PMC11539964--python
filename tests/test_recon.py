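"""OSEM reconstruction: EM properties and oracle equivalences."""

import numpy as np
import pytest

from petlesionsim import (MuMap, NormalizationMap, ReconParams, Sinogram,
                          SystemGeometry, VoxelGrid, default_target_sites,
                          derive_mrac_dixon, hu_to_mu_ctac,
                          make_pelvis_phantom, osem, sensitivity_image,
                          simulate_acquisition, voi_mask)
from petlesionsim.masks import sphere_mask
from petlesionsim.projection import back_project, forward_project_values
from petlesionsim.recon import subset_angle_indices


@pytest.fixture(scope="module")
def geom32(small_grid):
    return SystemGeometry.for_grid(small_grid, n_angles=32)


def _reference_mlem(y, mu, grid, geom, count_scale, iterations):
    """Plain MLEM written out long-hand: the oracle for the OSEM machinery.

    Uses the same projector but none of the subset/PSF code paths.
    """
    att = np.exp(-forward_project_values(mu.mu_per_cm, grid, geom) / 10.0)
    w = count_scale * att
    sens = back_project(w, grid, geom)
    x = np.ones(grid.shape)
    for _ in range(iterations):
        proj = w * forward_project_values(x, grid, geom)
        ratio = np.where(proj > 1e-12, y / np.maximum(proj, 1e-12), 0.0)
        x = np.where(sens > 1e-12,
                     x * back_project(w * ratio, grid, geom)
                     / np.maximum(sens, 1e-12), 0.0)
    return x


def _disc_acquisition(small_grid, geom32, noise=False, mu_val=0.0, seed=0):
    act = np.where(sphere_mask(small_grid, (6, -6), 110.0), 4.0, 0.0)
    mu = MuMap(small_grid, np.where(act > 0, mu_val, 0.0))
    norm = NormalizationMap.uniform(geom32)
    sino = simulate_acquisition(act, mu, norm, geom32, count_scale=2.0,
                                seed=seed, noise=noise)
    return act, mu, sino


def test_osem_one_subset_equals_reference_mlem(small_grid, geom32):
    act, mu, sino = _disc_acquisition(small_grid, geom32, noise=True,
                                      mu_val=0.0975, seed=4)
    params = ReconParams(mu_map=mu, iterations=5, subsets=1, psf_fwhm_mm=0.0)
    img = osem(sino, params, geom32, small_grid)
    ref = _reference_mlem(sino.values, mu, small_grid, geom32,
                          count_scale=2.0, iterations=5)
    np.testing.assert_allclose(img.activity_kbq_ml, ref, rtol=1e-10,
                               atol=1e-12)


def test_noiseless_reconstruction_conserves_activity(small_grid, geom32):
    """Count-conservation oracle: total recovered activity matches the truth
    within 2% after 10 MLEM iterations on noiseless data."""
    act, mu, sino = _disc_acquisition(small_grid, geom32, noise=False)
    params = ReconParams(mu_map=mu, iterations=10, subsets=1, psf_fwhm_mm=0.0)
    img = osem(sino, params, geom32, small_grid)
    assert img.activity_kbq_ml.sum() == pytest.approx(act.sum(), rel=0.02)


def test_em_output_is_non_negative(small_grid, geom32):
    _, mu, sino = _disc_acquisition(small_grid, geom32, noise=True,
                                    mu_val=0.0975, seed=8)
    img = osem(sino, ReconParams(mu_map=mu), geom32, small_grid)
    assert img.activity_kbq_ml.min() >= 0.0


def test_loglikelihood_monotone_over_full_iterations(small_grid, geom32):
    """EM guarantee: Poisson log-likelihood never decreases (matched mu-map,
    noiseless data, full-angle subsets)."""
    act, mu, sino = _disc_acquisition(small_grid, geom32, noise=False,
                                      mu_val=0.0975)
    y = sino.values
    att = np.exp(-forward_project_values(mu.mu_per_cm, small_grid, geom32)
                 / 10.0)

    def loglik(x):
        lam = 2.0 * att * forward_project_values(x, small_grid, geom32)
        pos = lam > 0
        return float((y[pos] * np.log(lam[pos]) - lam[pos]).sum()
                     - lam[~pos].sum())

    lls = []
    for it in range(1, 6):
        params = ReconParams(mu_map=mu, iterations=it, subsets=1,
                             psf_fwhm_mm=0.0)
        lls.append(loglik(osem(sino, params, geom32, small_grid)
                          .activity_kbq_ml))
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_sensitivity_uniform_inside_fov(small_grid, geom32):
    """Geometry oracle: with mu=0 and identity normalization the sensitivity
    image is flat (CoV < 5%) inside the inscribed circle."""
    mu0 = MuMap(small_grid, np.zeros(small_grid.shape))
    params = ReconParams(mu_map=mu0, subsets=1, psf_fwhm_mm=0.0)
    sens = sensitivity_image(params, geom32, small_grid, subset=0)
    inside = sphere_mask(small_grid, (0, 0), 0.9 * small_grid.fov_mm[0])
    vals = sens[inside]
    assert vals.std() / vals.mean() < 0.05
    assert np.all(vals > 0)


def test_subset_sensitivities_partition_full_sensitivity(small_grid, geom32):
    mu = MuMap(small_grid, np.where(sphere_mask(small_grid, (0, 0), 120.0),
                                    0.05, 0.0))
    params = ReconParams(mu_map=mu, subsets=4, psf_fwhm_mm=3.0)
    total = sum(sensitivity_image(params, geom32, small_grid, s)
                for s in range(4))
    full = sensitivity_image(
        ReconParams(mu_map=mu, subsets=1, psf_fwhm_mm=3.0),
        geom32, small_grid, 0)
    np.testing.assert_allclose(total, full, rtol=1e-8, atol=1e-10)


def test_larger_mu_lowers_sensitivity(small_grid, geom32):
    lo = MuMap(small_grid, np.full(small_grid.shape, 0.01))
    hi = MuMap(small_grid, np.full(small_grid.shape, 0.05))
    s_lo = sensitivity_image(ReconParams(mu_map=lo, subsets=1,
                                         psf_fwhm_mm=0.0),
                             geom32, small_grid, 0)
    s_hi = sensitivity_image(ReconParams(mu_map=hi, subsets=1,
                                         psf_fwhm_mm=0.0),
                             geom32, small_grid, 0)
    assert np.all(s_hi <= s_lo + 1e-12)


def test_subsets_must_divide_angles(small_grid, geom32):
    mu0 = MuMap(small_grid, np.zeros(small_grid.shape))
    sino = Sinogram(geom32, np.ones((32, geom32.n_radial_bins)),
                    kind="counts")
    with pytest.raises(ValueError):
        osem(sino, ReconParams(mu_map=mu0, subsets=5), geom32, small_grid)
    groups = subset_angle_indices(geom32, 4)
    assert sorted(i for g in groups for i in g) == list(range(32))


def test_all_zero_sinogram_warns_and_returns_zero(small_grid, geom32):
    mu0 = MuMap(small_grid, np.zeros(small_grid.shape))
    sino = Sinogram(geom32, np.zeros((32, geom32.n_radial_bins)),
                    kind="counts")
    with pytest.warns(UserWarning):
        img = osem(sino, ReconParams(mu_map=mu0, subsets=1), geom32,
                   small_grid)
    assert np.all(img.activity_kbq_ml == 0)


def test_bone_free_mu_map_underestimates_lesion_near_bone():
    """Reconstructing with the bone-free map must recover less activity in a
    lesion whose LORs cross bone (matched data, mismatched correction)."""
    grid = VoxelGrid((64, 64), (6.0, 6.0))
    geom = SystemGeometry.for_grid(grid, n_angles=48)
    ph = make_pelvis_phantom(grid, 5.0, seed=2)
    site = {s.name: s for s in default_target_sites(ph)}["acetabulum"]
    act = ph.activity_kbq_ml + np.where(
        sphere_mask(grid, site.center_mm, 12.0), 500.0, 0.0)
    mu_ctac = hu_to_mu_ctac(ph.hu, grid)
    mu_mrac = derive_mrac_dixon(ph.labels)
    norm = NormalizationMap.uniform(geom)
    sino = simulate_acquisition(act, mu_ctac, norm, geom, count_scale=0.5,
                                noise=False)
    rec_c = osem(sino, ReconParams(mu_map=mu_ctac), geom, grid)
    rec_m = osem(sino, ReconParams(mu_map=mu_mrac), geom, grid)
    voi = voi_mask(site.center_mm, 12.0, grid)
    assert rec_m.activity_kbq_ml[voi].mean() < rec_c.activity_kbq_ml[voi].mean()


def test_identical_mu_maps_give_bit_identical_reconstructions(small_grid,
                                                              geom32):
    _, mu, sino = _disc_acquisition(small_grid, geom32, noise=True,
                                    mu_val=0.0975, seed=12)
    params = ReconParams(mu_map=mu, iterations=2, subsets=4)
    a = osem(sino, params, geom32, small_grid)
    b = osem(sino, params, geom32, small_grid)
    assert np.array_equal(a.activity_kbq_ml, b.activity_kbq_ml)
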