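import numpy as np
import pandas as pd
import pytest

from mycoconcord import CohortConfig, FeatureTable, generate_cohort


@pytest.fixture(scope="session")
def paper_cohort():
    """Full-size cohort matching the study dimensions (144 samples, 1631 zOTUs)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast end-to-end runs."""
    return generate_cohort(
        CohortConfig(n_ibs=24, n_control=20, n_zotus_raw=300, target_prevalent=60,
                     richness_median=30, seed=7)
    )


@pytest.fixture()
def counts_table():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(8, 6)),
        index=[f"S{i}" for i in range(8)],
        columns=[f"F{j}" for j in range(6)],
    )
    data.iloc[0, 0] = 1  # ensure no all-zero rows/columns
    return FeatureTable(data.astype(float), units="counts")
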