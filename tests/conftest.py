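import pytest

from raphebg import State, default_parameters, steady_state_closed_form


@pytest.fixture(scope="session")
def defaults():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline(defaults):
    """Baseline equilibrium of the default calibration."""
    return steady_state_closed_form(defaults)


@pytest.fixture(scope="session")
def baseline_state(baseline) -> State:
    return baseline.state
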