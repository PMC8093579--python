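import numpy as np
import pytest

from crcsig.simulate import (
    CatalogSimSpec,
    CohortSimSpec,
    simulate_catalog,
    simulate_cohorts,
    toy_reference,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Toy reference genome + MAF records + per-SNV channel truth."""
    return toy_reference(seed=0, n_mismatch=2)


@pytest.fixture(scope="session")
def planted_catalog():
    """200 samples drawn from 3 planted signatures (the recovery setup)."""
    spec = CatalogSimSpec(
        n_samples=200,
        signatures=("Signature 1", "Signature 6", "Signature 10"),
        dirichlet_alpha=1.0,
        mutations_per_sample=100.0,
        seed=7,
    )
    return simulate_catalog(spec) + (spec,)


@pytest.fixture(scope="session")
def planted_cohorts():
    """Six expression cohorts with one planted prognostic pair."""
    spec = CohortSimSpec(seed=3, cohort_seeds=(1, 2, 3, 4, 5, 6))
    cohorts, truth = simulate_cohorts(spec)
    return cohorts, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
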