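import numpy as np
import pytest

from palpsim import (
    ControlConfig,
    IzhikevichParams,
    calibrate_gain,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(seed=42)


@pytest.fixture(scope="session")
def rs_params():
    return IzhikevichParams()


@pytest.fixture(scope="session")
def calibration(rs_params):
    # calibrated once per test session; top of the target range 100 Hz at 0.5 N
    return calibrate_gain(rs_params)


@pytest.fixture(scope="session")
def control_cfg():
    return ControlConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
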