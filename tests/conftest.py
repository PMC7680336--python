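import numpy as np
import pytest

from phylosym import get_fixture
from phylosym.generate import GeneratorConfig, random_tree


@pytest.fixture
def fig1():
    return get_fixture("fig1")[0]


@pytest.fixture
def k2p():
    return get_fixture("k2p")


def tree_sweep(count, leaf_range=(3, 12), seed0=0, max_children=4):
    """Deterministic stream of random trees cycling through leaf counts."""
    lo, hi = leaf_range
    trees = []
    for i in range(count):
        n = lo + i % (hi - lo + 1)
        trees.append(
            random_tree(GeneratorConfig(leaf_count=n, seed=seed0 + i, max_children=max_children))
        )
    return trees


# The four printed 5-taxon example matrices, frozen as the ground truth
# for the fig1 fixture (taxon order 1..5).
FIG1_MATRICES = {
    "alpha": np.array(
        [
            [-3, 0, 1, 1, 1],
            [0, -3, 1, 1, 1],
            [1, 1, -2, 0, 0],
            [1, 1, 0, -2, 0],
            [1, 1, 0, 0, -2],
        ]
    ),
    "beta": np.array(
        [
            [-1, 1, 0, 0, 0],
            [1, -1, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ]
    ),
    "gamma": np.array(
        [
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, -2, 1, 1],
            [0, 0, 1, -1, 0],
            [0, 0, 1, 0, -1],
        ]
    ),
    "delta": np.array(
        [
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, -1, 1],
            [0, 0, 0, 1, -1],
        ]
    ),
}
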