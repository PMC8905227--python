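import pytest
from hypothesis import settings

from lincforge.synthetic import SimulationConfig, generate_counts, generate_genome

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def genome(default_config):
    return generate_genome(default_config)


@pytest.fixture(scope="session")
def counts(genome):
    return generate_counts(genome)
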