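import numpy as np
import pytest

from lhcquench.exciton import build_site_hamiltonian, diagonalize
from lhcquench.quench import LutSiteConfig
from lhcquench.quench import _couplings_from_snapshot
from lhcquench.synthetic import FixtureSpec, generate_crystal_fixture
from lhcquench.vera import build_vera_rate_matrix, build_vibronic_basis, lutein_pyridine_params


@pytest.fixture(scope="session")
def params():
    """Reference lutein parameter set (a_max = 4)."""
    return lutein_pyridine_params()


@pytest.fixture(scope="session")
def basis(params):
    return build_vibronic_basis(params)


@pytest.fixture(scope="session")
def rate_matrix(basis):
    return build_vera_rate_matrix(basis)


@pytest.fixture(scope="session")
def small_params():
    """16-level variant (a_max = 1) for cheap propagation checks."""
    return lutein_pyridine_params(a_max=1)


@pytest.fixture(scope="session")
def crystal():
    """Calibrated crystal-like fixture: snapshot, lut configs, exciton basis."""
    snap, luts = generate_crystal_fixture(FixtureSpec())
    H = build_site_hamiltonian(snap, eps_r=2.0)
    exc = diagonalize(H, snap)
    resolved = [
        LutSiteConfig(lut_id=l.lut_id, site_couplings=_couplings_from_snapshot(snap, l.lut_id, 2.0))
        for l in luts
    ]
    return snap, resolved, exc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
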