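import pytest

from cidnp_screen import GeneratorParams, PipelineConfig, generate_library


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(random_seed=0)


@pytest.fixture(scope="session")
def library(config):
    """Default synthetic 40-molecule library plus its ground truth."""
    return generate_library(GeneratorParams(seed=0), config)


@pytest.fixture(scope="session")
def table(library):
    return library[0]
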