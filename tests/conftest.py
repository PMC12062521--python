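import numpy as np
import pytest
from hypothesis import settings

from nflref.simulate import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The study-condition generator: 223 subjects, decade counts
    57/58/59/37/12, 57% female, BCCG(mu=2.1*10^(0.012*age)*0.873^F, 0.38, 0.3)."""
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def cohort223(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def large_cohort():
    """A 4000-subject cohort with the same age structure, for fits that need
    tight sampling error."""
    from nflref.simulate import scaled_decade_counts

    cfg = SimulationConfig(decade_counts=scaled_decade_counts(4000), seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
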