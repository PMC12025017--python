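import pytest

from magvisc import default_coil, default_sensor, water


@pytest.fixture(scope="session")
def sensor():
    return default_sensor()


@pytest.fixture(scope="session")
def coil():
    return default_coil()


@pytest.fixture(scope="session")
def water_liquid():
    return water()
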