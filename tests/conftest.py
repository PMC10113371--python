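import numpy as np
import pandas as pd
import pytest

from mpsr.core import WILDTYPE_PARAMS
from mpsr.synthetic import CohortConfig, generate_cohort


def traces_frame(cells) -> pd.DataFrame:
    """Long-format trace table as written by the generator."""
    return pd.DataFrame({
        "cell_id": np.concatenate(
            [np.full(c.times.size, c.cell_id) for c in cells]),
        "time_h": np.concatenate([c.times for c in cells]),
        "fluorescence": np.concatenate([c.fluorescence for c in cells]),
    })


@pytest.fixture(scope="session")
def wildtype():
    return WILDTYPE_PARAMS


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = CohortConfig(n_cells=150, seed=42, noise_cv=0.0)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = CohortConfig(n_cells=200, seed=42, noise_cv=0.06)
    return cfg, generate_cohort(cfg)
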