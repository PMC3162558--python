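import random

import pytest

from pathevo.network import LayeredPathNetwork


@pytest.fixture
def rng():
    return random.Random(12345)


def build_two_path_net(p_green: float = 0.75) -> LayeredPathNetwork:
    """Four-layer network with a single branch: two paths with phenotypes
    0111 (probability p_green) and 0101 (probability 1 - p_green)."""
    net = LayeredPathNetwork(4)
    n1 = net.add_node(1, 0)
    n2 = net.add_node(2, 1)
    g3 = net.add_node(3, 1)
    p3 = net.add_node(3, 0)
    g4 = net.add_node(4, 1)
    p4 = net.add_node(4, 1)
    net.add_edge(net.start, n1, 1.0)
    net.add_edge(n1, n2, 1.0)
    net.add_edge(n2, g3, p_green)
    net.add_edge(n2, p3, 1.0 - p_green)
    net.add_edge(g3, g4, 1.0)
    net.add_edge(p3, p4, 1.0)
    return net


@pytest.fixture
def two_path_net():
    return build_two_path_net()
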