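import numpy as np
import pytest

import treemetrics as tm


@pytest.fixture(scope="session")
def eq3():
    """The worked 4-taxon matrix (taxa u, v, x, y), printed to 3 decimals."""
    return tm.worked_example()


@pytest.fixture(scope="session")
def saturating10():
    """The distortion d = 1 - exp(-t/10) whose inverse is -10*ln(1-d)."""
    return tm.NegLogSaturation(s=10, m=1)


def make_random_tree(n_leaves, seed, mean=0.05, law=None):
    cfg = tm.SimConfig(
        n_leaves=n_leaves,
        seed=seed,
        edge_length_law=law or ("exponential", {"mean": mean}),
    )
    return tm.random_tree(cfg)


@pytest.fixture
def random_tree_factory():
    return make_random_tree
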