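import pytest

from ligandsweep import (
    MATCHED_ALLELES,
    MISMATCH_ALLELES,
    SimConfig,
    build_profiles,
    simulate_experiment,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def proteome_and_abundance():
    """Default-scale synthetic proteome shared across tests (seed 0)."""
    return simulate_proteome(1000, 2.0, seed=0)


@pytest.fixture(scope="session")
def matched_profiles():
    return build_profiles(MATCHED_ALLELES, seed=11)


@pytest.fixture(scope="session")
def mismatch_profiles():
    return build_profiles(MISMATCH_ALLELES, seed=12)


@pytest.fixture(scope="session")
def default_experiment(proteome_and_abundance):
    proteome, abundance = proteome_and_abundance
    return simulate_experiment(SimConfig(seed=1), proteome, abundance)
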