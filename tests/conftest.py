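import dataclasses

import numpy as np
import pytest

from prosadapt.adaptation import compute_trace
from prosadapt.design import (Language, Phase, build_experiment_design,
                              build_training_design)
from prosadapt.synthetic_gaze import calibration_params, simulate_window_counts


@pytest.fixture(scope="session")
def exp1_design():
    return build_experiment_design(Language.EN_L2, Phase.EXPERIMENT1, seed=1)


@pytest.fixture(scope="session")
def training_design():
    return build_training_design(Language.EN_L2, seed=1)


@pytest.fixture(scope="session")
def session_phases(exp1_design, training_design):
    """Experiment 1 -> training -> experiment 2 with the experiment phases
    sharing one within-phase trial ordering (matched orderings)."""
    exp2 = dataclasses.replace(exp1_design, phase=Phase.EXPERIMENT2)
    return [exp1_design, training_design, exp2]


@pytest.fixture(scope="session")
def exp1_trace(exp1_design):
    return compute_trace([exp1_design], Language.EN_L2)


@pytest.fixture(scope="session")
def inhibition_counts(exp1_design, exp1_trace):
    """One simulated cohort with a strong inhibition effect and no
    facilitation (17 participants x 36 included trials)."""
    params = calibration_params(ic_weight=-2.0)
    return simulate_window_counts([exp1_design], exp1_trace, params,
                                  n_participants=17,
                                  rng=np.random.default_rng(101))
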