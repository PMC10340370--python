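"""OSEM reconstruction: oracle equivalence, conservation, artifact physics."""

import numpy as np
import pytest

from spectac import (
    AcqGeometry,
    ReconSettings,
    Role,
    Volume3,
    dew_scatter_estimate,
    osem_reconstruct,
)
from spectac.projsim import EnergyWindow, ProjectionSet, Projector
from spectac.recon import _support_mask, subset_views
from .conftest import make_disc_volume
from .oracles import dense_system_matrix, mlem_dense


def smooth_blob_activity(rng, shape=(1, 16, 16)):
    yy, xx = np.meshgrid(np.arange(16) - 7.5, np.arange(16) - 7.5, indexing="ij")
    r = np.hypot(yy, xx)
    act = np.where(r <= 5.5, 1.0 + 0.4 * np.cos(xx / 3.0), 0.0)
    return act[None] if len(shape) == 3 else act


class TestOsemCore:
    def test_zero_sinogram_reconstructs_to_zero(self, small_geom):
        peak = ProjectionSet(np.zeros((12, 1, 16)), small_geom)
        out = osem_reconstruct(
            peak, None, None, small_geom,
            ReconSettings(iterations=2, subsets=3, use_psf=False),
        )
        assert np.all(out.values == 0)

    def test_single_subset_matches_dense_mlem_oracle(self, small_geom, rng):
        shape = (1, 16, 16)
        act = smooth_blob_activity(rng)
        proj = Projector(small_geom, shape, (6.9,) * 3)
        y = proj.forward(act)
        A = dense_system_matrix(proj, shape)
        x0 = _support_mask(shape, (6.9,) * 3).ravel().astype(float)
        ref = mlem_dense(A, y.ravel(), x0, iterations=200)
        out = osem_reconstruct(
            ProjectionSet(y, small_geom), None, None, small_geom,
            ReconSettings(iterations=200, subsets=1, use_psf=False),
        )
        np.testing.assert_allclose(
            out.values.ravel(), ref, rtol=1e-6, atol=1e-6 * ref.max()
        )

    def test_count_preservation_each_full_iteration(self, small_geom, rng):
        # MLEM preserves total forward-projected counts after each iteration
        shape = (1, 16, 16)
        act = smooth_blob_activity(rng)
        proj = Projector(small_geom, shape, (6.9,) * 3)
        y = proj.forward(act)
        for iters in (1, 3):
            out = osem_reconstruct(
                ProjectionSet(y, small_geom), None, None, small_geom,
                ReconSettings(iterations=iters, subsets=1, use_psf=False),
            )
            assert proj.forward(out.values).sum() == pytest.approx(y.sum(), rel=1e-4)

    def test_nonnegativity(self, small_geom, rng):
        y = rng.random((12, 1, 16)) * 5
        out = osem_reconstruct(
            ProjectionSet(y, small_geom), None, None, small_geom,
            ReconSettings(iterations=3, subsets=4, use_psf=False),
        )
        assert np.all(out.values >= 0)

    def test_likelihood_nondecreasing_for_mlem(self, small_geom, rng):
        shape = (1, 16, 16)
        act = smooth_blob_activity(rng)
        proj = Projector(small_geom, shape, (6.9,) * 3)
        y = proj.forward(act)
        rng2 = np.random.default_rng(0)
        y_noisy = rng2.poisson(y * 50).astype(float)

        def loglik(x):
            fp = proj.forward(x) + 1e-12
            return float(np.sum(y_noisy * np.log(fp) - fp))

        lls = []
        for iters in (1, 2, 4, 8):
            out = osem_reconstruct(
                ProjectionSet(y_noisy, small_geom), None, None, small_geom,
                ReconSettings(iterations=iters, subsets=1, use_psf=False),
            )
            lls.append(loglik(out.values))
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_scatter_required_when_enabled(self, small_geom):
        peak = ProjectionSet(np.ones((12, 1, 16)), small_geom)
        with pytest.raises(ValueError, match="scatter"):
            osem_reconstruct(
                peak, None, None, small_geom,
                ReconSettings(use_scatter=True, use_psf=False),
            )

    def test_subset_partition_interleaves_views(self):
        parts = subset_views(60, 10)
        assert len(parts) == 10
        assert sorted(np.concatenate(parts)) == list(range(60))
        np.testing.assert_array_equal(parts[3], np.arange(3, 60, 10))


class TestAttenuationArtifact:
    @pytest.fixture(scope="class")
    def cylinder_setup(self):
        nz = 2
        disc = make_disc_volume(n=64, radius_vox=15.0, nz=nz)
        mu = np.where(disc.values > 0, 0.1537, 0.0)
        geom = AcqGeometry()
        proj = Projector(geom, disc.shape, disc.spacing_mm, acm_values=mu, psf=False)
        y = proj.forward(disc.values)
        return disc, mu, geom, y

    @staticmethod
    def center_edge_ratio(values):
        n = values.shape[1]
        c = 0.5 * (n - 1)
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        r = np.hypot(yy, xx)
        center = values[:, r <= 4].mean()
        edge = values[:, (r >= 10) & (r <= 13)].mean()
        return center / edge

    def test_nac_shows_cupping_ac_restores_uniformity(self, cylinder_setup):
        disc, mu, geom, y = cylinder_setup
        peak = ProjectionSet(y, geom)
        nac = osem_reconstruct(
            peak, None, None, geom,
            ReconSettings(iterations=3, subsets=10, use_psf=False),
        )
        acm = Volume3(mu, disc.spacing_mm, role=Role.MU_CM1)
        ac = osem_reconstruct(
            peak, None, acm, geom,
            ReconSettings(iterations=3, subsets=10, use_attenuation=True, use_psf=False),
        )
        assert self.center_edge_ratio(nac.values) < 1.0
        assert self.center_edge_ratio(ac.values) == pytest.approx(1.0, abs=0.05)

    def test_smoothed_acm_changes_uptake_less_than_5pct(self, cylinder_setup):
        from spectac.acmap import smooth_acm

        disc, mu, geom, y = cylinder_setup
        peak = ProjectionSet(y, geom)
        acm = Volume3(mu, disc.spacing_mm, role=Role.MU_CM1)
        acm_s = smooth_acm(acm, 13.0)
        settings = ReconSettings(
            iterations=3, subsets=10, use_attenuation=True, use_psf=False
        )
        ac = osem_reconstruct(peak, None, acm, geom, settings)
        ac_s = osem_reconstruct(peak, None, acm_s, geom, settings)
        inner = disc.values > 0
        rel = abs(ac_s.values[inner].mean() - ac.values[inner].mean()) / ac.values[inner].mean()
        assert rel < 0.05


class TestDewScatter:
    def test_zero_k_disables_correction(self, small_geom):
        sw = ProjectionSet(np.ones((12, 1, 16)), small_geom, EnergyWindow.SCATTER)
        est = dew_scatter_estimate(sw, k=0.0)
        assert np.all(est.counts == 0)

    def test_window_width_scaling(self, small_geom):
        # counts of 8 scaled by 21/8 keV -> 21 at k = 1
        sw = ProjectionSet(np.full((12, 1, 16), 8.0), small_geom, EnergyWindow.SCATTER)
        est = dew_scatter_estimate(sw, k=1.0)
        np.testing.assert_allclose(est.counts, 21.0, rtol=1e-12)

    def test_linear_in_k(self, small_geom, rng):
        sw = ProjectionSet(rng.random((12, 1, 16)), small_geom, EnergyWindow.SCATTER)
        a = dew_scatter_estimate(sw, k=0.3).counts
        b = dew_scatter_estimate(sw, k=0.6).counts
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_photopeak_window_rejected(self, small_geom):
        pk = ProjectionSet(np.ones((12, 1, 16)), small_geom, EnergyWindow.PHOTOPEAK)
        with pytest.raises(ValueError, match="SCATTER"):
            dew_scatter_estimate(pk, k=0.5)
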