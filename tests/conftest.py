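import numpy as np
import pytest

from dynalign import (
    SGParams,
    TemporalNetwork,
    WalkParams,
    generate_base_network,
)


@pytest.fixture
def toy_network() -> TemporalNetwork:
    """3 nodes, 2 time points: snapshot 0 = {ab, bc}, snapshot 1 = {ac}."""
    return TemporalNetwork(
        name="toy",
        nodes=frozenset(),
        events=frozenset({("a", "b", 0), ("b", "c", 0), ("a", "c", 1)}),
    )


@pytest.fixture
def small_base() -> TemporalNetwork:
    return generate_base_network(30, 2, 3, 0.05, seed=11)


@pytest.fixture
def fast_walk_params() -> WalkParams:
    return WalkParams(walks_per_node=5, walk_length=20)


@pytest.fixture
def fast_sg_params() -> SGParams:
    return SGParams(dim=32, epochs=2, seed=3)


def relabeled_copy(net: TemporalNetwork, prefix: str = "x"):
    """An exact copy under fresh node ids, with the relabel ground truth."""
    mapping = {n: prefix + n for n in net.nodes}
    truth = {prefix + n: n for n in net.nodes}
    return net.relabel(mapping, name="copy"), truth
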