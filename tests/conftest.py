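import numpy as np
import pytest

from spectac import AcqGeometry, PhantomSpec, Role, Volume3, generate_phantom


@pytest.fixture(scope="session")
def base_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_pair(base_spec):
    """One deterministic CT/activity pair on the full grid."""
    return generate_phantom(base_spec, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_geom() -> AcqGeometry:
    """A light acquisition geometry for projector/reconstruction unit tests."""
    return AcqGeometry(n_views=12, n_bins=16)


def make_disc_volume(n=64, radius_vox=15.0, nz=1, value=1.0, spacing=6.9) -> Volume3:
    """Uniform disc activity centred on the grid."""
    c = 0.5 * (n - 1)
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    sl = np.where(np.hypot(yy, xx) <= radius_vox, value, 0.0)
    return Volume3(np.repeat(sl[None], nz, axis=0), (spacing,) * 3, role=Role.ACTIVITY)
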