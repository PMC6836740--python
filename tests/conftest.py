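import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pollenphase import (
    RunConfig,
    SimConfig,
    simulate_all,
    simulate_diploid_genome,
)

settings.register_profile(
    "pkg",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pkg")


SMALL_SIM = dict(
    n_chromosomes=2,
    chrom_length=60_000,
    n_cells=12,
    n_fragments=60,
    fragment_length_range=(8_000, 20_000),
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Paper-like rates at desk scale (2 x 60 kb chromosomes)."""
    return SimConfig(seed=7, **SMALL_SIM)


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    """Full coverage, no genotype error: the exact-recovery limit."""
    return SimConfig(
        seed=7, coverage_range=(1.0, 1.0), genotype_error_rate=0.0, **SMALL_SIM
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_diploid_genome(small_config)


@pytest.fixture(scope="session")
def noise_free_sim(noise_free_config):
    """(genome, gametes, observations, bacs) in the noise-free limit."""
    return simulate_all(noise_free_config)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(genome, gametes, observations, bacs) under paper-like noise."""
    return simulate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
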