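import pytest

from mhspc_cea import calibrate_arm_curves, default_inputs


@pytest.fixture()
def us_inputs():
    return default_inputs("US")


@pytest.fixture()
def china_inputs():
    return default_inputs("China")


@pytest.fixture()
def us_curves(us_inputs):
    return calibrate_arm_curves(us_inputs.evidence, us_inputs.config)
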