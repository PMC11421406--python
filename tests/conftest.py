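import numpy as np
import pandas as pd
import pytest

from speechresp import CohortConfig, MissingnessPlan, simulate_cohort
from speechresp import pipeline as _pipeline


@pytest.fixture(scope="session")
def small_config():
    """A 4-listener, 2-masker cohort: 4 x 2 x 5 x 5 = 200 trials."""
    return CohortConfig(
        n_nh=2, n_hi=2,
        maskers={"OLnoise": 2, "ISTS": 1},
        missingness=MissingnessPlan(0, 0, 0, 0),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """One full default-study pipeline run, shared across tests."""
    return _pipeline.run(_pipeline.PipelineConfig(seed=1))
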