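import numpy as np
import pytest
from hypothesis import settings

from hecm.synthetic import ScenarioConfig, generate_fingerprints, generate_toxicity

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_scenario():
    return ScenarioConfig(seed=0)


@pytest.fixture(scope="session")
def scenario_data(default_scenario):
    """One default-scenario realisation: (table, toxicity, X, Y)."""
    table = generate_fingerprints(default_scenario)
    tox = generate_toxicity(table, default_scenario)
    Y = tox.group_means()[["alt_mean", "ast_mean"]].to_numpy()
    return table, tox, table.areas, Y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
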