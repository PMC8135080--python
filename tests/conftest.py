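import numpy as np
import pytest

from platemark.cohort import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def small_design():
    """Fast cohort: few proteins, strong planted structure."""
    return CohortDesign(
        n_proteins=120,
        n_cluster1=15,
        n_cluster2=12,
        n_cluster3=8,
        panel_size=4,
        n_corr=10,
        effect_size=1.5,
        noise_sd=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return generate_cohort(small_design)


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-shaped cohort: 3000 proteins, planted 160/135/65 clusters."""
    return generate_cohort(CohortDesign(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
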