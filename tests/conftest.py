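"""Shared fixtures: one error-free simulated dataset reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

from pirnaphase.simulate import (SimConfig, build_genome, emit_reads,
                                 simulate_biogenesis)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_cfg():
    """Reduced-depth configuration with no sequencing errors, so truth
    comparisons are exact; PCR duplicates kept to exercise deduplication."""
    return SimConfig(
        seed=7,
        small_depth=20_000,
        long_depth=3_000,
        sequencing_error_rate=0.0,
        pcr_duplicate_rate=0.2,
        n_small_replicates=1,
        n_long_replicates=1,
    )


@pytest.fixture(scope="session")
def genome_build(clean_cfg):
    return build_genome(clean_cfg)


@pytest.fixture(scope="session")
def truth(clean_cfg, genome_build):
    return simulate_biogenesis(clean_cfg, genome_build)


@pytest.fixture(scope="session")
def readset(clean_cfg, genome_build, truth):
    return emit_reads(truth, clean_cfg, genome_build, replicate=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
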