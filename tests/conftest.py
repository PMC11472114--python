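import pytest

from vulnmap import (
    PipelineConfig,
    compute_indicators,
    default_registry,
    generate_census_counts,
    generate_region,
    vulnerability_index,
)

# fixed study-condition seeds used across the suite
REGION_SEED = 1
CENSUS_SEED = 2
FLOOD_SEED = 3
TEMP_SEED = 4


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def region_small():
    """10x10 lattice: cheap fixture for structural tests."""
    return generate_region(10, seed=REGION_SEED)


@pytest.fixture(scope="session")
def region_400():
    """20x20 = 400 areas: the planted-truth recovery study size."""
    return generate_region(20, seed=REGION_SEED)


@pytest.fixture(scope="session")
def census_400(region_400, registry):
    return generate_census_counts(region_400, registry, effect_size=1.0, seed=CENSUS_SEED)


@pytest.fixture(scope="session")
def indicators_400(census_400, registry):
    return compute_indicators(census_400, registry)


@pytest.fixture(scope="session")
def vulnerability_400(indicators_400, registry):
    return vulnerability_index(indicators_400, registry)
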