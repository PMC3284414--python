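import pytest

from eqtariff import (
    US_D1O_TARIFF,
    enumerate_states,
    reparameterize,
)


@pytest.fixture(scope="session")
def us_tariff():
    """The published US D1-style tariff at 3-decimal precision."""
    return US_D1O_TARIFF


@pytest.fixture(scope="session")
def us_d1c_tariff():
    """Its exact constant-term re-expression."""
    return reparameterize(US_D1O_TARIFF)


@pytest.fixture(scope="session")
def all_states():
    return enumerate_states(include_perfect=True)


@pytest.fixture(scope="session")
def impaired_states():
    return enumerate_states(include_perfect=False)
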