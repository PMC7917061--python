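import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_gdina_dataset():
    """High-quality G-DINA dataset with known truth (K=4, N=2000)."""
    from cdmdim import SimCondition, generate_dataset

    cond = SimCondition(K=4, IQ=0.80, N=2000, JK=4, AC=0.30, AT=0.0, M="GDINA")
    return generate_dataset(cond, 20240)
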