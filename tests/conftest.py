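import numpy as np
import pytest

from grfm.body import default_instrumentation, load_deleva_table, scale_body
from grfm.pipeline import PipelineConfig, run_predict
from grfm.synthetic import (
    PendulumChain,
    SyntheticTrialSpec,
    default_segment_lengths,
    generate_static_pose,
    generate_trial,
)

BW = 77.34 * 9.81


@pytest.fixture(scope="session")
def deleva():
    return load_deleva_table()


@pytest.fixture(scope="session")
def default_body(deleva):
    return scale_body(
        deleva,
        77.34,
        1.81,
        default_segment_lengths(1.81),
        instrumentation=default_instrumentation(),
    )


@pytest.fixture(scope="session")
def trial():
    """Noiseless normal-walking trial (6 strides at 240 Hz)."""
    return generate_trial(SyntheticTrialSpec())


@pytest.fixture(scope="session")
def prediction_unfiltered(trial):
    return run_predict(
        trial.kinematics,
        trial.points,
        trial.body,
        PipelineConfig(cutoff_hz=None),
        sta=trial.spec.sta,
    )


@pytest.fixture(scope="session")
def prediction_filtered(trial):
    return run_predict(
        trial.kinematics, trial.points, trial.body, PipelineConfig(), sta=trial.spec.sta
    )


@pytest.fixture(scope="session")
def static_trial():
    return generate_static_pose()


@pytest.fixture(scope="session")
def pendulum():
    chain = PendulumChain()
    t = np.linspace(0.1, 1.1, 241)
    return chain, t, chain.kinematics(t), chain.body_model()
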