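import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ivcfit import CohortSpec, cohort_spec, simulate_cohort

settings.register_profile("repro", derandomize=True, max_examples=60)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def swine_cohort() -> pd.DataFrame:
    """One seeded swine-profile cohort (n=24) reused across tests."""
    return simulate_cohort(cohort_spec("swine", seed=20240101), group_labels=["phi32", "phi20"])


@pytest.fixture(scope="session")
def noiseless_spec() -> CohortSpec:
    """Perfect circularization: post diameters equal the true equivalent diameter."""
    return cohort_spec("swine", seed=7, anisotropy=0.0, remodel_sd=0.0, edge_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
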