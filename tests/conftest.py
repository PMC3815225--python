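import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    from auxiaa.config import PipelineConfig

    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def family():
    """Default synthetic 34-gene family bundle (sequences + truth)."""
    from auxiaa.synthetic_data import simulate_family_sequences

    return simulate_family_sequences(seed=20240901 % (2**31))


@pytest.fixture(scope="session")
def family_plans():
    from auxiaa.synthetic_data import default_family_plan

    return {p.name: p for p in default_family_plan()}
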