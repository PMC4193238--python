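import numpy as np
import pytest

from sparsesim.benchmark import BenchmarkSet, build_network
from sparsesim.simulator import NeuronParams


@pytest.fixture(scope="session")
def tiny_bench() -> BenchmarkSet:
    """A miniature benchmark configuration for fast wiring tests."""
    return BenchmarkSet(set_id=2, K=20, K_exc=16, K_inh=4, J_E=50.0, g=7.0, eta=1.2)


@pytest.fixture(scope="session")
def tiny_network(tiny_bench):
    """Small static-weight network shared by simulator tests."""
    net = build_network(tiny_bench, N=60, n_vp=4, seed=7)
    net.stdp_enabled = False
    return net


@pytest.fixture(scope="session")
def default_neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
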