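import numpy as np
import pytest

from spikemeta.neurons import NetworkWeights, NeuronParams


@pytest.fixture
def params():
    return NeuronParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net(rng):
    """A 4-neuron recurrent net with 3 inputs and 2 readouts, driven hard
    enough that spikes occur."""
    w = NetworkWeights.initialize(3, 4, 2, rng)
    w.w_in *= 3.0
    return w


def make_input(rng, batch=2, n_in=3, T=40, p=0.3):
    return (rng.random((batch, n_in, T)) < p).astype(float)
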