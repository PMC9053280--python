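import numpy as np
import pytest

from breathtdm.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact scan-level cohort shared by read-only tests."""
    cfg = CohortConfig(n_subjects=8, visits_per_subject=2,
                       n_endogenous_features=16, n_nuisance_features=10,
                       seed=42)
    measurements, truth, db = simulate_cohort(cfg)
    return cfg, measurements, truth, db


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
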