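import numpy as np
import pytest

from nadnirs.params import AnalysisParams
from nadnirs.stimuli import build_stimulus_lists, schedule_session
from nadnirs.synthdata import SimParams, make_probe_layout, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def neonate_layout():
    return make_probe_layout("neonate")


@pytest.fixture(scope="session")
def neonate_schedule():
    rng = np.random.default_rng(7)
    lists = build_stimulus_lists(rng)
    return schedule_session("neonate", lists[0], rng)


@pytest.fixture(scope="session")
def quiet_sim_params():
    """Simulator settings without artifacts, for clean-path tests."""
    import dataclasses
    return dataclasses.replace(SimParams(), p_trial_artifact=0.0,
                               background_spike_rate=0.0, saturation_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Three simulated neonate recordings with default (artifact-bearing) settings."""
    return simulate_cohort(3, "neonate", seed=101)
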