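import numpy as np
import pytest
from hypothesis import settings

from popvcf import SimParams, simulate_mito, simulate_population

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def tiny_params():
    """Small, fast panel: 8 samples, two short chromosomes, one dup region."""
    return SimParams(
        n_samples=8,
        chrom_lengths={"1": 60_000, "2": 40_000},
        n_ref_private=4,
        dup_regions=[("2", 1, 8_000, 8.0)],
        coverage_mean=20.0,
        seed=7,
    )


@pytest.fixture
def tiny_sim(tiny_params):
    return simulate_population(tiny_params)


@pytest.fixture(scope="session")
def study_params():
    """Study-condition panel: 101 samples, ~1e5 sites, coverage 20."""
    return SimParams(coverage_mean=20.0, seed=101)


@pytest.fixture(scope="session")
def study_sim(study_params):
    return simulate_population(study_params)


@pytest.fixture(scope="session")
def study_mito(study_params):
    return simulate_mito(study_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
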