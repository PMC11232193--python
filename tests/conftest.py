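import numpy as np
import pytest

from cernet import (
    SimulationConfig,
    build_initial_triplets,
    perturb_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def demo_cohort():
    """A small seeded cohort: 5 planted triplets among 60 decoys."""
    cfg = SimulationConfig(
        n_normal=30, n_tumor=25, n_planted=5,
        n_decoy_mirna=15, n_background=5, seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_triplets(demo_cohort):
    _, cohort = demo_cohort
    genes = set(cohort.expression.gene_ids)
    return build_initial_triplets(cohort.lnc_mi, cohort.mrna_mi, genes, genes, genes)


@pytest.fixture(scope="session")
def demo_records(demo_cohort, demo_triplets):
    _, cohort = demo_cohort
    records, excluded = perturb_cohort(cohort.expression, demo_triplets)
    return records, excluded


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
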