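import pytest
from hypothesis import HealthCheck, settings

from metasecretome.model import ModelParams
from metasecretome.synth import generate_community, shear_and_clone

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def community():
    """Small synthetic community shared across tests."""
    return generate_community(n_replicons=2, n_orfs=200,
                              secretome_fraction=0.20, seed=11)


@pytest.fixture(scope="session")
def clone_library(community):
    return shear_and_clone(community, n_clones=3000, seed=11)
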