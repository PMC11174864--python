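import numpy as np
import pytest

from mvmwgl.synthetic import CohortSpec, generate_cohort, generate_fixture


@pytest.fixture(scope="session")
def two_cliques():
    return generate_fixture("two-cliques")


@pytest.fixture(scope="session")
def four_groups_small():
    return generate_fixture("four-groups-small")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort for training-loop tests (fast, non-trivial)."""
    spec = CohortSpec(
        n_patients=120,
        n_genes=30,
        n_informative_genes=21,
        n_groups=4,
        group_survival_means=(10.0, 30.0, 70.0, 120.0),
        survival_noise_sd=5.0,
        module_sizes=(10, 10, 10),
        p_within=0.4,
        p_between=0.05,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
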