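import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_macular_pair():
    """Zero-noise, zero-motion default scene with ground truth (session-cached)."""
    from faleak import synthetic

    return synthetic.generate_fa_pair(synthetic.ScenarioParams(noise_sd=0.0, seed=3))
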