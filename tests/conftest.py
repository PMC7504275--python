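import pytest

from tgoil import io as tgio
from tgoil.simulate import SimConfig


@pytest.fixture(scope="session")
def standards():
    """Packaged reference-standard table (17 TGs)."""
    return tgio.load_standard_table()


@pytest.fixture(scope="session")
def profiles():
    """Packaged pure-oil and blend profiles."""
    return tgio.load_reference_profiles()


@pytest.fixture(scope="session")
def ref_model():
    """Identification chart fitted from the packaged standards."""
    return tgio.fit_reference_model()


@pytest.fixture()
def sim_cfg():
    """Default simulator config (fresh per test; tests may mutate/replace)."""
    return SimConfig.default(seed=0)


@pytest.fixture(scope="session")
def oil_tg_names(profiles):
    return sorted(set(profiles["RRO"].contents) | set(profiles["OO"].contents))
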