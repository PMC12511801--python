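import numpy as np
import pytest

import surfconn as sc


@pytest.fixture(scope="session")
def ico2():
    return sc.generate_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return sc.generate_icosphere(3)


@pytest.fixture(scope="session")
def ico2_basis(ico2):
    return sc.compute_spectrum(ico2, 162)


@pytest.fixture(scope="session")
def ico3_basis(ico3):
    return sc.compute_spectrum(ico3, 400)


@pytest.fixture(scope="session")
def ico5_basis():
    """First 501 eigenpairs on the subdiv-5 unit icosphere (10242 vertices).

    Expensive (shift-invert Lanczos); shared by the Weyl-law and
    sphere-identity checks.
    """
    mesh = sc.generate_icosphere(5)
    return mesh, sc.compute_spectrum(mesh, 501)


@pytest.fixture(scope="session")
def two_bundle(ico3_basis):
    """The packaged two-bundle scenario on the subdiv-3 icosphere."""
    from surfconn.simulate import default_two_bundle_mixture

    density, mixture = default_two_bundle_mixture(ico3_basis)
    return density, mixture


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
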