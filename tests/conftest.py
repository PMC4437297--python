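import numpy as np
import pytest

import extremis as ex


@pytest.fixture(scope="session", autouse=True)
def _warm_kernel():
    """Compile the relaxation kernel once so timings reflect the physics."""
    g = ex.complete_graph(3)
    st = ex.OpinionState(np.array([0.9, 0.8, 0.1]), g)
    ex.relax(st, ex.ModelParams(a=1.0))


@pytest.fixture
def k3_state():
    g = ex.complete_graph(3)
    return ex.OpinionState(np.array([0.9, 0.8, 0.1]), g)


@pytest.fixture
def path4_state():
    """Path A-B-C-D with a mix of extreme and moderate opinions."""
    g = ex.path_graph(4)
    return ex.OpinionState(np.array([0.9, 0.6, 0.3, 0.8]), g)


def random_graph_and_opinions(rng, n_max=30, k_max=5.0):
    n = int(rng.integers(3, n_max))
    g = ex.generate_er(n, min(float(rng.uniform(1.5, k_max)), n - 1),
                       int(rng.integers(1 << 30)))
    q = rng.uniform(-1.0, 1.0, n)
    return g, q
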