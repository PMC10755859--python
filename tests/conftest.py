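import numpy as np
import pytest

from strainflow.synthetic_cohort import (
    CohortConfig,
    simulate_catalog,
    simulate_cohort,
    simulate_pileups,
    simulate_strain_genomes,
)


@pytest.fixture(scope="session")
def catalog():
    return simulate_catalog(n_genes=30, length_range=(300, 600), seed=1)


@pytest.fixture(scope="session")
def strains(catalog):
    return simulate_strain_genomes(catalog, seed=2)


@pytest.fixture(scope="session")
def small_cohort(strains):
    cfg = CohortConfig(arm_sizes=(25, 25, 25), seed=3)
    return simulate_cohort(cfg, strains)


@pytest.fixture(scope="session")
def small_pileups(small_cohort):
    return simulate_pileups(small_cohort, error_rate=0.002, seed=4)


@pytest.fixture(scope="session")
def trial_cohort(strains):
    """Cohort at the analyzed-population scale (218 infants, three arms)."""
    cfg = CohortConfig(arm_sizes=(75, 73, 70), seed=5)
    return simulate_cohort(cfg, strains)


@pytest.fixture(scope="session")
def trial_pileups(trial_cohort):
    return simulate_pileups(trial_cohort, error_rate=0.002, seed=6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
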