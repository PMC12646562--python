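import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import inpheld as ip

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def norms():
    return ip.placeholder_norms()


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (70 patients, 39 shunted, 5
    latent nonresponders), shared read-only across tests."""
    records, truth = ip.generate_cohort(ip.default_study_config(seed=7))
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
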