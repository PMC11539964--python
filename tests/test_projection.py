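"""System model: Radon projection, attenuation factors, counts, noise."""

import math

import numpy as np
import pytest

from petlesionsim import (MuMap, NormalizationMap, Sinogram, SystemGeometry,
                          VoxelGrid, add_sinograms, attenuation_factors,
                          forward_project, simulate_acquisition)
from petlesionsim.masks import sphere_mask
from petlesionsim.projection import back_project, forward_project_values


@pytest.fixture(scope="module")
def grid():
    return VoxelGrid((64, 64), (3.0, 3.0))


@pytest.fixture(scope="module")
def geom(grid):
    return SystemGeometry.for_grid(grid, n_angles=48)


def test_geometry_invariants(grid):
    with pytest.raises(ValueError):
        SystemGeometry.for_grid(grid, n_angles=8)
    g = SystemGeometry.for_grid(grid)
    assert g.n_angles == 180
    assert g.n_radial_bins * g.radial_spacing_mm >= math.sqrt(2) * g.fov_mm
    assert all(b > a for a, b in zip(g.angles_deg, g.angles_deg[1:]))
    with pytest.raises(ValueError):  # radial window too narrow
        SystemGeometry(n_angles=48, n_radial_bins=10, radial_spacing_mm=3.0,
                       fov_mm=192.0)


def test_zero_volume_projects_to_zero(grid, geom):
    sino = forward_project(np.zeros(grid.shape), grid, geom)
    assert sino.kind == "line_integral"
    assert np.all(sino.values == 0)


def test_forward_projection_is_linear(grid, geom):
    rng = np.random.default_rng(0)
    x = rng.random(grid.shape)
    y = rng.random(grid.shape)
    lhs = forward_project_values(2.5 * x - 0.5 * y, grid, geom)
    rhs = (2.5 * forward_project_values(x, grid, geom)
           - 0.5 * forward_project_values(y, grid, geom))
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


def test_disc_projection_conserves_total_per_angle(grid, geom):
    """Analytic oracle: the bin sum of each view equals value x disc area."""
    disc = np.where(sphere_mask(grid, (12.0, -9.0), 90.0), 2.0, 0.0)
    sino = forward_project(disc, grid, geom)
    total = disc.sum() * grid.voxel_volume  # value*mm^2
    per_angle = sino.values.sum(axis=1) * geom.radial_spacing_mm
    np.testing.assert_allclose(per_angle, total, rtol=0.01)


def test_point_source_traces_sinusoid(grid, geom):
    """Analytic oracle: maxima follow r = d cos(theta - phi)."""
    pt = np.zeros(grid.shape)
    pt[44, 22] = 1.0
    x0 = grid.axis_coords(0)[44]
    y0 = grid.axis_coords(1)[22]
    sino = forward_project(pt, grid, geom)
    loci = geom.radial_coords_mm[np.argmax(sino.values, axis=1)]
    expected = np.array([x0 * math.cos(math.radians(a))
                         + y0 * math.sin(math.radians(a))
                         for a in geom.angles_deg])
    assert np.abs(loci - expected).max() <= geom.radial_spacing_mm


def test_attenuation_identity_at_zero_mu(grid, geom):
    mu = MuMap(grid, np.zeros(grid.shape))
    f = attenuation_factors(mu, geom)
    assert np.all(f.values == 1.0)


def test_attenuation_central_ray_closed_form():
    """exp(-0.0975/cm * 20 cm) = exp(-1.95) through a water disc."""
    grid = VoxelGrid((128, 128), (3.0, 3.0))
    geom = SystemGeometry.for_grid(grid, n_angles=96)
    mu = MuMap(grid, np.where(sphere_mask(grid, (0.0, 0.0), 200.0),
                              0.0975, 0.0))
    f = attenuation_factors(mu, geom)
    central = f.values[:, geom.n_radial_bins // 2]
    expected = math.exp(-1.95)
    assert np.abs(central / expected - 1).max() < 0.05
    assert abs(central.mean() / expected - 1) < 0.02


def test_attenuation_monotone_in_mu(grid, geom):
    rng = np.random.default_rng(1)
    base = rng.random(grid.shape) * 0.05
    small = MuMap(grid, base)
    large = MuMap(grid, base + 0.02)
    fs = attenuation_factors(small, geom).values
    fl = attenuation_factors(large, geom).values
    assert np.all(fl <= fs + 1e-12)
    assert np.all((fs > 0) & (fs <= 1.0))


def test_noiseless_acquisition_equals_scaled_projection(grid, geom):
    rng = np.random.default_rng(2)
    act = rng.random(grid.shape)
    mu0 = MuMap(grid, np.zeros(grid.shape))
    norm = NormalizationMap.uniform(geom)
    lam = simulate_acquisition(act, mu0, norm, geom, count_scale=7.0,
                               noise=False)
    assert lam.kind == "expected_counts"
    np.testing.assert_allclose(lam.values,
                               7.0 * forward_project_values(act, grid, geom),
                               rtol=1e-12)


def test_poisson_draw_reproducible_and_integer(grid, geom):
    act = np.where(sphere_mask(grid, (0, 0), 120.0), 5.0, 0.0)
    mu = MuMap(grid, np.where(act > 0, 0.0975, 0.0))
    norm = NormalizationMap.uniform(geom)
    a = simulate_acquisition(act, mu, norm, geom, 0.5, seed=9, noise=True)
    b = simulate_acquisition(act, mu, norm, geom, 0.5, seed=9, noise=True)
    c = simulate_acquisition(act, mu, norm, geom, 0.5, seed=10, noise=True)
    assert a.kind == "counts"
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)
    assert np.all(a.values == np.rint(a.values))


def test_poisson_mean_and_variance_match_expectation():
    """Monte-Carlo oracle: across 200 draws the per-bin sample mean stays
    within 3 standard errors of lambda for >= 99% of bins, and the pooled
    variance/mean ratio is ~1."""
    grid = VoxelGrid((32, 32), (6.0, 6.0))
    geom = SystemGeometry.for_grid(grid, n_angles=24)
    act = np.where(sphere_mask(grid, (0, 0), 120.0), 5.0, 0.0)
    mu = MuMap(grid, np.zeros(grid.shape))
    norm = NormalizationMap.uniform(geom)
    lam = simulate_acquisition(act, mu, norm, geom, 0.2, noise=False).values
    draws = np.stack([
        simulate_acquisition(act, mu, norm, geom, 0.2, seed=s,
                             noise=True).values
        for s in range(200)])
    hot = lam > 1.0
    se = np.sqrt(lam[hot] / 200)
    frac_ok = np.mean(np.abs(draws.mean(0)[hot] - lam[hot]) <= 3 * se)
    assert frac_ok >= 0.99
    ratio = draws.var(0)[hot].sum() / lam[hot].sum()
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_add_sinograms_rules(grid, geom):
    rng = np.random.default_rng(3)
    a = Sinogram(geom, np.rint(rng.random((geom.n_angles,
                                           geom.n_radial_bins)) * 9),
                 kind="counts")
    zero = Sinogram(geom, np.zeros_like(a.values), kind="counts")
    s = add_sinograms(a, zero)
    np.testing.assert_array_equal(s.values, a.values)
    assert np.all(s.values == np.rint(s.values))
    b = Sinogram(geom, a.values, kind="expected_counts")
    with pytest.raises(ValueError):
        add_sinograms(a, b)
    other = SystemGeometry.for_grid(grid, n_angles=24)
    c = Sinogram(other, np.zeros((24, geom.n_radial_bins)), kind="counts")
    with pytest.raises(ValueError):
        add_sinograms(a, c)


def test_expected_counts_additive_over_activities(grid, geom):
    """Linearity oracle: acquisition of summed activities equals the sum of
    the separate noiseless acquisitions."""
    rng = np.random.default_rng(4)
    act1 = rng.random(grid.shape)
    act2 = rng.random(grid.shape)
    mu = MuMap(grid, np.full(grid.shape, 0.01))
    norm = NormalizationMap.uniform(geom)
    s12 = simulate_acquisition(act1 + act2, mu, norm, geom, 3.0, noise=False)
    s1 = simulate_acquisition(act1, mu, norm, geom, 3.0, noise=False)
    s2 = simulate_acquisition(act2, mu, norm, geom, 3.0, noise=False)
    np.testing.assert_allclose(s12.values, add_sinograms(s1, s2).values,
                               rtol=1e-10)


def test_back_projection_is_exact_adjoint(grid, geom):
    rng = np.random.default_rng(5)
    x = rng.random(grid.shape)
    q = rng.random((geom.n_angles, geom.n_radial_bins))
    lhs = float((forward_project_values(x, grid, geom) * q).sum())
    rhs = float((x * back_project(q, grid, geom)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-10)


def test_thin_3d_volume_projects_slicewise(geom, grid):
    grid3 = VoxelGrid((64, 64, 3), (3.0, 3.0, 3.0))
    vol = np.zeros(grid3.shape)
    vol[:, :, 1] = np.where(sphere_mask(grid, (0, 0), 60.0), 1.0, 0.0)
    sino = forward_project(vol, grid3, geom)
    assert sino.values.shape == (geom.n_angles, geom.n_radial_bins, 3)
    assert np.all(sino.values[:, :, 0] == 0)
    np.testing.assert_allclose(
        sino.values[:, :, 1],
        forward_project(vol[:, :, 1], grid, geom).values)
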