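import numpy as np
import pytest
from hypothesis import settings

from snpher import CohortConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Ascertained admixed case-control cohort, desk-sized."""
    cfg = CohortConfig(n_samples=300, m_variants=800, n_causal=100, seed=7)
    g, phenotypes, covar, truth = generate_cohort(cfg)
    return cfg, g, phenotypes, covar, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240618)
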