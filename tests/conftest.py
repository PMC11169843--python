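import numpy as np
import pytest

import dtscnn as d


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dtc_net():
    """A 6-neuron dual-threshold network: 4 conv membranes + 2 outputs."""
    arch = d.parse_arch("1dtc3-2fc", (2, 2, 1))
    params = d.init_params(arch, seed=3, leak=0.5, threshold_init=0.5)
    return arch, params


@pytest.fixture
def mixed_net():
    """dtc -> spiking fc -> output; 7 neurons on a 1x1x2 input."""
    arch = d.parse_arch("2dtc1-3fc-2fc", (1, 1, 2))
    params = d.init_params(arch, seed=5, leak=0.5, threshold_init=0.5)
    return arch, params
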