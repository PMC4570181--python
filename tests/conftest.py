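import numpy as np
import pytest

from bregtomo import (OpticalProperties, generate_cylinder_mesh,
                      make_phantom, reproduce_two_source_study)


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse cylinder mesh (radius 5, height 10, ~1.6 mm edges)."""
    return generate_cylinder_mesh(5.0, 10.0, 1.6, seed=0)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Coarse 4-tissue cylinder phantom for fast end-to-end tests."""
    return make_phantom("cylinder_4tissue", resolution=2.0, seed=0)


@pytest.fixture(scope="session")
def homogeneous_optics():
    return OpticalProperties(mu_a=0.01, mu_s_prime=1.0)


@pytest.fixture(scope="session")
def two_source_study():
    """The full two-source reproduction run shared by acceptance tests."""
    data, results = reproduce_two_source_study(resolution=1.1, seed=0)
    return data, results


@pytest.fixture
def rng():
    return np.random.default_rng(0)
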