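import pytest
from hypothesis import HealthCheck, settings

from ribotx.simulate import SimulationConfig, simulate_all

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study conditions."""
    config = SimulationConfig(seed=7)
    genome, genes, truth, profiles, mrna, rpf = simulate_all(config)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "profiles": profiles,
        "mrna": mrna,
        "rpf": rpf,
    }
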