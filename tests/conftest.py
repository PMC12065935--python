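import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

import tumorkinetics as tk


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated trial reused by cohort-level tests."""
    scn = tk.db03_like_scenario(seed=77, n_per_arm={"T-DXd": 60, "control": 60})
    return tk.simulate_cohort(scn)


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    results = tk.fit_cohort(small_cohort.trajectories)
    return tk.results_to_frame(results)
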