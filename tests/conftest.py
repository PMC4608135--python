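import dataclasses

import numpy as np
import pytest

import voltmem as vm


@pytest.fixture(scope="session")
def amphibian():
    return vm.load_conditions("amphibian")


@pytest.fixture(scope="session")
def mammalian():
    return vm.load_conditions("mammalian")


@pytest.fixture(scope="session")
def nav16():
    return vm.load_channel("nav16_reduced")


@pytest.fixture(scope="session")
def mammalian_nav16_model(nav16, mammalian):
    """Nav1.6 + leak under mammalian conditions, full-precision reversals."""
    return vm.build_model([nav16], mammalian)


@pytest.fixture(scope="session")
def printed_mammalian_model(nav16, mammalian):
    """The tabulated reduced model: E_Na = 60 mV, E_leak = -67 mV exactly."""
    ch = dataclasses.replace(nav16, fixed_reversal_mv=60.0)
    return vm.build_model([(ch, 2.0)], mammalian, leak_reversal=-67.0)


@pytest.fixture(scope="session")
def printed_amphibian_model(nav16, amphibian):
    """Amphibian counterpart with E_Na = -19 mV, E_leak = +45 mV exactly."""
    ch = dataclasses.replace(nav16, fixed_reversal_mv=-19.0)
    return vm.build_model([(ch, 2.0)], amphibian, leak_reversal=45.0)


def eq5_field(v, gbar_na=2.0, gbar_leak=0.2, e_na=60.0, e_leak=-67.0, c=1.0):
    """Independent scalar evaluation of the reduced Nav1.6 + leak field."""
    v = np.asarray(v, float)
    i = gbar_na / (1.0 + np.exp(-0.1565 * (v + 17.0))) * (v - e_na)
    i = i + gbar_leak * (v - e_leak)
    return -i / c
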