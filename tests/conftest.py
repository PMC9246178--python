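import numpy as np
import pytest

from rmfnet.network import NetworkSpec, NeuronParams, PoissonDrive


@pytest.fixture(scope="session")
def neuron():
    """The standard single-neuron parameter set (h=1 Hz, a=0.1, tau=10 ms)."""
    return NeuronParams(h=1.0, a=0.1, tau=0.01)


@pytest.fixture(scope="session")
def exc_drive():
    """1 kHz excitatory Poisson input with unit weight."""
    return PoissonDrive(channels=((1000.0, 1.0),))


@pytest.fixture(scope="session")
def single_neuron_net():
    """Isolated neuron as a 1-node network (drive supplied externally)."""
    return NetworkSpec(params=[NeuronParams(h=1.0, a=0.1, tau=0.01)],
                       weights=np.zeros((1, 1)))
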