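"""Shared fixtures: synthetic cohorts at the default study conditions.

Session-scoped so the (few-second) cohort simulations are paid once and
reused across test modules.
"""

from __future__ import annotations

import pytest

from methvar import SimulationConfig, run_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full default cohort: 28 samples, 120 planted blocks (20/20/20/60)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    ds = default_dataset
    return run_pipeline(
        ds.reads, ds.counts, ds.genotypes, ds.snp_positions, ds.phenotypes
    )


@pytest.fixture(scope="session")
def block_fixture_dataset():
    """The 20-planted-block genome used for caller recovery checks."""
    return simulate_dataset(
        SimulationConfig(
            seed=11,
            n_blocks_per_class={"HVMR": 5, "hypoCMR": 5, "hyperCMR": 5, "neutral": 5},
            chrom_length=40_000,
            n_meqtl=0,
            n_trait_pairs=0,
        )
    )
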