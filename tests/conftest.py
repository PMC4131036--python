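import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allfoodseq import GenomeSpec, MixtureSpec, generate_panel, simulate_reads
from allfoodseq.mapper import SeedIndex

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """Three 20 kb genomes from one ancestor at 5% per-site divergence."""
    specs = [
        GenomeSpec(name, 20_000, divergence=0.05, ancestor="anc", seed=i)
        for i, name in enumerate(["alpha", "beta", "gamma"])
    ]
    return generate_panel(specs, shared_ancestor_seed=101)


@pytest.fixture(scope="session")
def small_index(small_panel):
    return SeedIndex(small_panel, seed_length=20, read_length=100, k_max=3)


@pytest.fixture(scope="session")
def small_reads(small_panel):
    mix = MixtureSpec(
        {"alpha": 20.0, "beta": 30.0, "gamma": 50.0},
        total_reads=6000,
        error_rate=0.01,
        seed=5,
    )
    return simulate_reads(small_panel, mix)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
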