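import numpy as np
import pandas as pd
import pytest

from hipscpipe.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort shared by read-only tests."""
    cfg = SimulationConfig(n_genes=800, n_donors_case=6, n_donors_control=6,
                           lines_per_donor=2, icc_donor=0.1, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def balanced_metadata(n_donors: int, k: int) -> pd.DataFrame:
    donors = np.repeat([f"d{i:02d}" for i in range(n_donors)], k)
    return pd.DataFrame({"donor": donors},
                        index=[f"s{i:03d}" for i in range(n_donors * k)])
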