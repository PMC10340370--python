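"""Forward projector: closed forms, adjointness, noise and scatter models."""

import numpy as np
import pytest

from spectac import (
    AcqGeometry,
    EnergyWindow,
    Role,
    Volume3,
    forward_project,
    sample_counts,
    simulate_scatter_window,
)
from spectac.projsim import Projector
from .conftest import make_disc_volume


class TestForwardProject:
    def test_zero_activity_projects_to_zero(self, small_geom):
        act = Volume3(np.zeros((2, 16, 16)), role=Role.ACTIVITY)
        proj = forward_project(act, None, small_geom)
        assert np.all(proj.counts == 0)

    def test_linearity(self, small_geom, rng):
        a = rng.random((2, 16, 16))
        b = rng.random((2, 16, 16))
        p = Projector(small_geom, (2, 16, 16), (6.9,) * 3)
        np.testing.assert_allclose(
            p.forward(2.0 * a + 3.0 * b),
            2.0 * p.forward(a) + 3.0 * p.forward(b),
            rtol=1e-12,
        )

    def test_uniform_disc_central_chord(self):
        # central ray through a unit disc of radius R sums ~ 2R/voxel values
        radius_vox = 15.0
        disc = make_disc_volume(n=64, radius_vox=radius_vox)
        geom = AcqGeometry(n_views=8)
        proj = forward_project(disc, None, geom)
        central = proj.counts[:, 0, 31:33].max(axis=1)
        np.testing.assert_allclose(central, 2 * radius_vox, rtol=0.02)

    def test_point_source_beer_lambert(self):
        # odd grid puts a voxel exactly at the centre of the attenuating disc;
        # the disc is drawn with subvoxel partial-volume edges so the voxelised
        # attenuator represents the ideal circle of the closed form
        n = 63
        c = (n - 1) // 2
        spacing = 6.9
        geom = AcqGeometry(n_views=8, n_bins=n)
        pt = np.zeros((1, n, n))
        pt[0, c, c] = 1.0
        mu0, radius_mm = 0.15, 80.0
        oversample = 4
        coords = (np.arange(n * oversample) / oversample - 0.5 + 0.5 / oversample) - c
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        fine = (np.hypot(yy, xx) * spacing <= radius_mm).astype(float)
        mu = mu0 * fine.reshape(n, oversample, n, oversample).mean(axis=(1, 3))[None]
        p_att = Projector(geom, (1, n, n), (spacing,) * 3, acm_values=mu)
        p_free = Projector(geom, (1, n, n), (spacing,) * 3)
        ratio = p_att.forward(pt).max(axis=(1, 2)) / p_free.forward(pt).max(axis=(1, 2))
        np.testing.assert_allclose(ratio, np.exp(-mu0 * radius_mm / 10.0), rtol=0.02)

    def test_attenuation_monotonicity(self, small_geom, rng):
        act = rng.random((1, 16, 16))
        mu = rng.random((1, 16, 16)) * 0.02
        p_lo = Projector(small_geom, (1, 16, 16), (6.9,) * 3, acm_values=mu)
        mu_hi = mu.copy()
        mu_hi[0, 8, 8] += 0.1
        p_hi = Projector(small_geom, (1, 16, 16), (6.9,) * 3, acm_values=mu_hi)
        assert np.all(p_hi.forward(act) <= p_lo.forward(act) + 1e-12)

    def test_rotational_symmetry_of_disc_profiles(self):
        disc = make_disc_volume(n=64, radius_vox=12.0)
        geom = AcqGeometry(n_views=12)
        proj = forward_project(disc, None, geom).counts[:, 0, :]
        totals = proj.sum(axis=1)
        assert totals.std() / totals.mean() < 0.01

    def test_misaligned_volumes_rejected(self, small_geom):
        act = Volume3(np.zeros((2, 16, 16)), role=Role.ACTIVITY)
        acm = Volume3(np.zeros((3, 16, 16)), role=Role.MU_CM1)
        with pytest.raises(ValueError, match="aligned"):
            forward_project(act, acm, small_geom)


class TestAdjointness:
    @pytest.mark.parametrize("psf,with_att", [(False, False), (True, False), (True, True)])
    def test_forward_and_backprojector_are_exact_transposes(self, rng, psf, with_att):
        geom = AcqGeometry(n_views=10, n_bins=16)
        shape = (3, 16, 16)
        mu = rng.random(shape) * 0.03 if with_att else None
        p = Projector(geom, shape, (6.9,) * 3, acm_values=mu, psf=psf)
        x = rng.random(shape)
        y = rng.random((10, 3, 16))
        lhs = np.sum(p.forward(x) * y)
        rhs = np.sum(x * p.adjoint(y))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestSampleCounts:
    def test_zero_expectation_bins_always_zero(self, small_geom):
        from spectac.projsim import ProjectionSet

        expected = np.zeros((12, 2, 16))
        expected[0, 0, 8] = 100.0
        proj = ProjectionSet(expected, small_geom)
        for seed in range(5):
            noisy = sample_counts(proj, 1000.0, seed=seed)
            assert np.all(noisy.counts[expected == 0] == 0)

    def test_total_scaled_to_request(self, small_geom, rng):
        from spectac.projsim import ProjectionSet

        proj = ProjectionSet(rng.random((12, 2, 16)), small_geom)
        noisy = sample_counts(proj, 5e4, seed=3)
        # Poisson total ~ 5e4 +/- ~4 sd
        assert abs(noisy.counts.sum() - 5e4) < 4 * np.sqrt(5e4)

    def test_mean_matches_expectation_over_seeds(self, small_geom):
        from spectac.projsim import ProjectionSet

        expected = np.zeros((12, 1, 16))
        expected[0, 0, 8] = 7.0
        expected[3, 0, 4] = 3.0
        proj = ProjectionSet(expected, small_geom)
        total = expected.sum()
        draws = np.stack(
            [sample_counts(proj, total, seed=s).counts for s in range(400)]
        )
        bin_mean = draws[:, 0, 0, 8].mean()
        se = np.sqrt(7.0 / 400)
        assert abs(bin_mean - 7.0) < 4 * se

    def test_deterministic_per_seed(self, small_geom, rng):
        from spectac.projsim import ProjectionSet

        proj = ProjectionSet(rng.random((12, 2, 16)) * 10, small_geom)
        a = sample_counts(proj, 1e4, seed=11)
        b = sample_counts(proj, 1e4, seed=11)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_nonpositive_total_rejected(self, small_geom):
        from spectac.projsim import ProjectionSet

        proj = ProjectionSet(np.ones((12, 2, 16)), small_geom)
        with pytest.raises(ValueError):
            sample_counts(proj, 0.0, seed=1)


class TestScatterWindow:
    def test_zero_fraction_gives_zero_window(self, small_geom, rng):
        from spectac.projsim import ProjectionSet

        proj = ProjectionSet(rng.random((12, 2, 16)), small_geom)
        sw = simulate_scatter_window(proj, 0.0)
        assert np.all(sw.counts == 0)
        assert sw.window == EnergyWindow.SCATTER

    def test_mass_ratio_preserved_by_convolution(self):
        # interior source: total scatter = sf/(1-sf) * total primaries
        geom = AcqGeometry(n_views=4)
        from spectac.projsim import ProjectionSet

        counts = np.zeros((4, 16, 64))
        counts[:, 6:10, 28:36] = 10.0
        proj = ProjectionSet(counts, geom)
        sw = simulate_scatter_window(proj, 0.3, broaden_fwhm_mm=20.0)
        assert sw.counts.sum() == pytest.approx((0.3 / 0.7) * counts.sum(), rel=1e-3)

    def test_zero_broadening_is_scaled_copy(self, small_geom, rng):
        from spectac.projsim import ProjectionSet

        proj = ProjectionSet(rng.random((12, 2, 16)), small_geom)
        sw = simulate_scatter_window(proj, 0.25, broaden_fwhm_mm=0.0)
        np.testing.assert_allclose(sw.counts, (0.25 / 0.75) * proj.counts, rtol=1e-12)

    def test_fraction_bounds_enforced(self, small_geom):
        from spectac.projsim import ProjectionSet

        proj = ProjectionSet(np.ones((12, 2, 16)), small_geom)
        with pytest.raises(ValueError):
            simulate_scatter_window(proj, 1.0)
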