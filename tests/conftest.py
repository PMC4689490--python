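import numpy as np
import pandas as pd
import pytest

from epiburden.bands import DEFAULT_BANDS
from epiburden.disease_model import HazardSchedule
from epiburden.synthetic import default_spec, expected_counts, observed_rates

NB = len(DEFAULT_BANDS)


@pytest.fixture(scope="session")
def cohort_spec():
    """Agincourt-scale study conditions (2 sexes x 6 bands, 4-year follow-up)."""
    return default_spec(seed=20151223)


@pytest.fixture(scope="session")
def noise_free_rates(cohort_spec):
    """Band-level observed rates implied exactly by the generating hazards."""
    return observed_rates(expected_counts(cohort_spec))


@pytest.fixture
def constant_schedule():
    """Constant-hazard schedule with a known sojourn time 1/(r+m+f)."""
    return HazardSchedule(
        DEFAULT_BANDS,
        np.full(NB, 2e-4),
        np.full(NB, 0.04),
        np.full(NB, 0.01),
        np.full(NB, 0.01),
    )


def single_sex_rates(rates: pd.DataFrame, sex: str) -> tuple[pd.DataFrame, np.ndarray]:
    grp = rates[rates["sex"] == sex].reset_index(drop=True)
    return grp.drop(columns=["sex", "age_lo", "age_hi", "mortality"]), grp["mortality"].to_numpy()
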