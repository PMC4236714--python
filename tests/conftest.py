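import pytest
from hypothesis import settings

import bphbia

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config():
    """Complete seeded configuration with synthetic transition matrices."""
    return bphbia.default_config(seed=11)


@pytest.fixture(scope="session")
def equal_arms_config(base_config):
    """Both arms on the SoC matrix: any impact is pure drug-cost difference."""
    return base_config.copy_with(
        **{"transitions.fdc": base_config.transitions.soc.model_dump()})


@pytest.fixture(scope="session")
def null_market_config(base_config):
    """All-zero uptake and switching: the introduction world collapses to SoC."""
    return base_config.copy_with(
        **{"market.uptake_share": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
           "market.switch_rate": {1: 0.0, 2: 0.0, 3: 0.0}})
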