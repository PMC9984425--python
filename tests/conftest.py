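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


@pytest.fixture(scope="session")
def small_panel():
    """Two moderately LD-correlated blocks of 5, 800 samples."""
    from pleioscan.synthetic import simulate_reference_panel

    return simulate_reference_panel(
        800, [5, 5], within_block_ld=0.5, seed=42
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
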