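import numpy as np
import pytest

from snpower import ScenarioConfig, substream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binary_config():
    return ScenarioConfig(maf=0.1, effect_size=1.5, outcome_type="binary",
                          n=2000, prevalence=0.1, baseline_or=10.0,
                          reps=200, seed=7)


@pytest.fixture
def continuous_config():
    return ScenarioConfig(maf=0.1, effect_size=0.5, outcome_type="continuous",
                          n=200, trait_sd=1.0, reps=200, seed=7)
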