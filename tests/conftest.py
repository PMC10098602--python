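import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def electrostatics():
    from phaseslab.energy import ElectrostaticsSpec
    return ElectrostaticsSpec()


@pytest.fixture(scope="session")
def pair_table():
    from phaseslab.params import PairTable
    return PairTable.from_table()
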