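import numpy as np
import pytest

from spikegrad import LayerParams, NeuronConfig, SpikeRaster, SurrogateSpec


def random_lif_stack(rng, sizes, T, alpha, theta=1.0, family="exponential",
                     scale=1.0, spike_prob=0.3, weight_std=None):
    """Random dense LIF/IF stack plus a Poisson input raster and loss seed."""
    surrogate = SurrogateSpec(family=family, scale=scale)
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        std = weight_std if weight_std is not None else 1.5 / np.sqrt(n_in)
        layers.append(LayerParams(weights=rng.normal(0.0, std, size=(n_out, n_in)),
                                  neuron=NeuronConfig.lif(alpha, theta, T),
                                  surrogate=surrogate))
    raster = SpikeRaster((rng.random((T, sizes[0])) < spike_prob).astype(np.int8))
    e_out = rng.normal(size=(T, sizes[-1]))
    return layers, raster, e_out


def random_config(rng, trial, max_n=8, max_t=32, max_layers=3):
    """One draw from the standard random-configuration suite: L in {1,2,3},
    layer widths <= 8, T <= 32, alpha in {1, 0.9, 0.5}, exponential or
    constant surrogate, Poisson input."""
    L = int(rng.integers(1, max_layers + 1))
    sizes = [int(rng.integers(1, max_n + 1)) for _ in range(L + 1)]
    T = int(rng.integers(2, max_t + 1))
    alpha = (1.0, 0.9, 0.5)[trial % 3]
    family = ("exponential", "constant")[trial % 2]
    scale = float(rng.uniform(0.2, 1.5))
    return random_lif_stack(rng, sizes, T, alpha, family=family, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
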