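import numpy as np
import pandas as pd
import pytest

import longdens as ld
from longdens.pipeline import preprocess


@pytest.fixture
def tiny_cohort():
    """Two women, five screens, handwritten values."""
    screens = pd.DataFrame(
        {
            "woman_id": ["a", "a", "a", "b", "b"],
            "exam_time": [0.0, 1.8, 3.5, 0.0, 2.0],
            "age": [50.0, 51.8, 55.0 - 1.5, 62.0, 64.0],
            "bmi": [24.0, 25.0, 25.5, 31.0, np.nan],
            "birads": [3, 3, 2, 1, 2],
        }
    )
    outcomes = pd.DataFrame(
        {
            "woman_id": ["a", "b"],
            "exit_time": [6.0, 4.5],
            "event": [1, 0],
            "censor_reason": ["none", "admin_end"],
        }
    )
    return ld.CohortTable(screens, outcomes)


@pytest.fixture(scope="session")
def true_params():
    return ld.SimConfig().lmm_params()


@pytest.fixture(scope="session")
def sim_cohort():
    """Small discretized simulated cohort, preprocessed."""
    cohort, _ = ld.simulate_cohort(ld.SimConfig(n_women=400, seed=42))
    return preprocess(cohort)


@pytest.fixture(scope="session")
def sim_fit(sim_cohort):
    """Mixed-model fit on the small simulated cohort (shared, slow)."""
    return ld.DensityMixedModel(sim_cohort).fit()


@pytest.fixture(scope="session")
def sim_estimates(sim_cohort):
    """(lmm results, cut points, estimates) on the small simulated cohort."""
    from longdens.pipeline import fit_and_estimate

    return fit_and_estimate(sim_cohort)
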