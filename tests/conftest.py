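import pytest
from hypothesis import settings

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """One small seeded synthetic study shared by read-only tests."""
    from cnvassoc import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(rng_seed=11, n_library_cnps=60))
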