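import numpy as np
import pytest

from flowcascade import FlowAbundanceCascade, ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def mountainous_data():
    """Default-size mountainous scenario (10 sites, 16 models, 12 species)."""
    return generate_scenario(ScenarioConfig.mountainous(seed=1))


@pytest.fixture(scope="session")
def mountainous_results(mountainous_data):
    return FlowAbundanceCascade.from_scenario(mountainous_data).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
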