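import numpy as np
import pytest

import traitpaths as tp
from traitpaths.ctmc import N_RATES, N_STATES


@pytest.fixture
def cherry():
    return tp.read_newick("(A:1,B:1);")


@pytest.fixture
def quartet():
    return tp.read_newick("((A:0.3,B:0.5):0.4,(C:0.6,D:0.2):0.3);")


@pytest.fixture
def q_random():
    rng = np.random.default_rng(42)
    return rng.uniform(0.2, 2.0, size=N_RATES)


def random_instance(rng, max_tips=6):
    """A random (tree, Q, states) triple for oracle comparisons."""
    n = int(rng.integers(2, max_tips + 1))
    tree = tp.simulate_yule_tree(n, seed=int(rng.integers(2**31)), scale_depth=1.0)
    q = rng.uniform(0.05, 3.0, size=N_RATES)
    Q = tp.build_rate_matrix(q)
    states = {}
    for label in tree.tip_labels():
        if rng.random() < 0.15:
            states[label] = tp.UNKNOWN
        else:
            states[label] = int(rng.integers(N_STATES))
    return tree, Q, states
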