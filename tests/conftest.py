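import numpy as np
import pandas as pd
import pytest

from lacodose.cohort import CohortSpec, ParameterDistribution, default_cohort_spec, sample_cohort


@pytest.fixture(scope="session")
def mean_patient() -> pd.DataFrame:
    """Single patient at the published distribution means."""
    return pd.DataFrame(
        {
            "weight_kg": [75.40],
            "vd_per_kg": [0.61],
            "clnr_ml_min": [16.60],
            "sieving_coefficient": [0.78],
        }
    )


@pytest.fixture(scope="session")
def degenerate_spec() -> CohortSpec:
    """Cohort spec with all SDs zero: every patient equals the means."""
    return CohortSpec(
        n=50,
        seed=0,
        weight_dist=ParameterDistribution(75.40, 0.0, lower=40.0),
        vd_per_kg_dist=ParameterDistribution(0.61, 0.0, lower=0.40, upper=1.00),
        clnr_dist=ParameterDistribution(16.60, 0.0, lower=3.33, upper=26.67),
        sc_dist=ParameterDistribution(0.78, 0.0, lower=0.0, upper=1.0),
    )


@pytest.fixture(scope="session")
def cohort_10k() -> pd.DataFrame:
    """One 10,000-patient cohort at the published distributions."""
    return sample_cohort(default_cohort_spec(n=10_000, seed=2024))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
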