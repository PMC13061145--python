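import pytest
from hypothesis import HealthCheck, settings

from adipoplacenta import simulate_counts, small_config

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset shared across tests (seeded)."""
    cfg = small_config(seed=11)
    counts, metadata, truth = simulate_counts(cfg)
    return cfg, counts, metadata, truth
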