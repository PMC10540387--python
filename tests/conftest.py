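import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230928)


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic synthetic dataset shared across read-only tests."""
    from nirscalib import GeneratorConfig, simulate_dataset

    cfg = GeneratorConfig(n_samples=120, n_points=300, seed=11)
    return cfg, simulate_dataset(cfg)
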