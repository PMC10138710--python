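import logging

import pytest

import guildnet as gn
from guildnet.network import CoAbundanceNetwork

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def cohort29():
    """Default synthetic cohort at the emulated study's size."""
    return gn.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort60():
    """Same generative conditions at n = 60 for higher-power recovery checks."""
    cfg = gn.CohortConfig(n_samples=60, n_increase=27, n_decrease=33)
    return gn.generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def solution29(cohort29):
    return CoAbundanceNetwork(cohort29.features).fit()


@pytest.fixture(scope="session")
def solution60(cohort60):
    return CoAbundanceNetwork(cohort60.features).fit()
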