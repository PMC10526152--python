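import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230918)


@pytest.fixture
def published_matrices():
    from kinfuse import pilot
    return pilot.PUBLISHED_MATRICES


@pytest.fixture
def subjects():
    from kinfuse import pilot
    return pilot.SUBJECTS
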