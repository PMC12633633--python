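import numpy as np
import pytest

from ppglm.basis import BasisSet
from ppglm.io import SpikePopulation
from ppglm.simulate import simulate_all_to_one


@pytest.fixture(scope="session")
def gl3():
    """Default generalized-Laguerre basis: J=3, H=5 ms, alpha=2, c=1.5."""
    return BasisSet(kind="gl", J=3, H=0.005)


@pytest.fixture(scope="session")
def small_pop():
    """A small random 3-neuron population with spikes clear of the edges."""
    rng = np.random.default_rng(42)
    T = 3.0
    trains = [np.sort(rng.uniform(0.05, T - 0.05, rng.poisson(10 * T)))
              for _ in range(3)]
    return SpikePopulation(trains, T)


@pytest.fixture(scope="session")
def sim100():
    """All-to-one simulation, 8 neurons, 100 s (target is neuron 7)."""
    pop, truth = simulate_all_to_one(T=100.0, seed=1)
    return pop, truth
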