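import pytest

from ihrcost import country_x_coarse, country_x_fine


@pytest.fixture(scope="session")
def coarse():
    return country_x_coarse()


@pytest.fixture(scope="session")
def fine():
    return country_x_fine()
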