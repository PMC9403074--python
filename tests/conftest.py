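import numpy as np
import pytest
from hypothesis import settings

import aortaref as ar

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sanitized_registry():
    return ar.published_registry("sanitized")


@pytest.fixture(scope="session")
def printed_registry():
    return ar.published_registry("as_printed")


@pytest.fixture(scope="session")
def dmax_ga_chart(sanitized_registry):
    return sanitized_registry[("Dmax", "GA")]


@pytest.fixture(scope="session")
def cohort490():
    """One fixed synthetic study cohort (n = 490, uniform GA, sanitized truth)."""
    return ar.simulate_cohort(ar.GeneratorConfig(n=490, seed=11)).records


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
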