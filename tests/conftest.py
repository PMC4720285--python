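import numpy as np
import pytest

import nflink as nfl


@pytest.fixture
def fig1():
    return nfl.fig1_network()


def random_graph_corpus(count=20, max_n=40, seed=0, min_n=4):
    """Erdős–Rényi graphs with varied size and density, including sparse
    ones with isolated nodes."""
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(count):
        n = int(rng.integers(min_n, max_n + 1))
        p = float(rng.uniform(0.05, 0.5))
        graphs.append(nfl.erdos_renyi(n, p, seed=int(rng.integers(2**31))))
    return graphs


@pytest.fixture(scope="session")
def small_corpus():
    return random_graph_corpus(count=12, max_n=25, seed=101)
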