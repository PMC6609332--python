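import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nprrquant as q

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    """Standard paradigm: four 18 s bursts at 70 Hz, 42 s intervals, 1 fps."""
    return q.make_protocol()


@pytest.fixture(scope="session")
def noiseless_params():
    return q.TraceSimParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_nprr_dff(protocol, noiseless_params):
    return q.nprr_dff_noiseless(protocol, noiseless_params)


@pytest.fixture(scope="session")
def noiseless_nprr_trace(protocol, noiseless_nprr_dff):
    from nprrquant.traces import DFFTrace

    return DFFTrace(
        frames=protocol.frame_times(),
        dff=noiseless_nprr_dff,
        baseline_value=100.0,
        baseline_window=(0.0, 28.0),
    )


@pytest.fixture(scope="session")
def noiseless_gcamp_trace(protocol, noiseless_params):
    from nprrquant.traces import DFFTrace

    return DFFTrace(
        frames=protocol.frame_times(),
        dff=np.asarray(q.gcamp_dff_noiseless(protocol, noiseless_params)),
        baseline_value=100.0,
        baseline_window=(0.0, 28.0),
    )
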