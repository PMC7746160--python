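import pytest

from ricespace import CultivarParams, generate_synthetic_climate


@pytest.fixture(scope="session")
def params():
    return CultivarParams()


@pytest.fixture(scope="session")
def climate120():
    """Default full-season synthetic climate shared across tests."""
    return generate_synthetic_climate(120, 42)


@pytest.fixture(scope="session")
def climate_short():
    """A 40-day series for cheap developmental tests."""
    return generate_synthetic_climate(40, 7)
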