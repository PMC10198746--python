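import numpy as np
import pytest

from netreduce import (
    BlockSpec,
    NodePartition,
    WeightedDigraph,
    directed_sbm,
    positivize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fig2a_spec():
    """Two equal communities of 100 nodes with asymmetric block densities."""
    return BlockSpec(
        sizes=np.array([100, 100]),
        density=np.array([[0.3, 0.05], [0.1, 0.6]]),
    )


def random_positive_net(rng, n, low=0.1, high=2.0):
    return WeightedDigraph(rng.uniform(low, high, (n, n)))


def random_grouped_net(rng, sizes, density=0.4):
    """Positivized binary SBM with the given group sizes."""
    k = len(sizes)
    spec = BlockSpec(sizes=np.array(sizes), density=np.full((k, k), density))
    return positivize(directed_sbm(spec, rng), 1e-4), spec.partition()


@pytest.fixture
def small_positive_net(rng):
    return random_positive_net(rng, 8)


@pytest.fixture
def three_group_partition():
    return NodePartition.from_sizes([4, 3, 5])
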