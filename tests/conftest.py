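import pytest

import citysweat as cs


@pytest.fixture(scope="session")
def fixture_city():
    """Small deterministic 64×64 city shared across tests."""
    return cs.generate_city(cs.fixture_city_spec(seed=7))


@pytest.fixture(scope="session")
def weather_default():
    return cs.generate_weather(cs.WeatherSpec(seed=7), year=2020)


@pytest.fixture(scope="session")
def weather_quiet():
    """Noise-free weather: pure seasonal sinusoids."""
    return cs.generate_weather(cs.WeatherSpec(noise_sd=0.0, seed=7), year=2020)


@pytest.fixture(scope="session")
def season_configs():
    return cs.default_season_configs()
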