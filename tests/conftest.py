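import numpy as np
import pytest

from spindlesim.params import build_reference_params, reduced_accuracy_control


@pytest.fixture()
def reference_params():
    return build_reference_params()


@pytest.fixture()
def batch_params():
    """Reference set with the coarse-timestep batch control settings."""
    p = build_reference_params()
    p.control = reduced_accuracy_control(kmc_interval=20)
    return p


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))
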