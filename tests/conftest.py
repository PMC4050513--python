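import numpy as np
import pandas as pd
import pytest

from genokrige import DistrictSpec, generate_cohort
from genokrige.synthetic import OutcomeSpec, simulate_outcomes


@pytest.fixture(scope="session")
def district():
    return DistrictSpec()


@pytest.fixture(scope="session")
def small_cohort(district):
    """120 children with standardised exposures and simulated outcomes."""
    cohort = generate_cohort(district, n_per_stratum=60, seed=42)
    rng = np.random.default_rng(7)
    for col in ("z_formaldehyde", "z_no2"):
        z = rng.standard_normal(len(cohort))
        cohort[col] = (z - z.mean()) / z.std(ddof=1)
    return simulate_outcomes(cohort, OutcomeSpec(), seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
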