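import numpy as np
import pytest

from haplink.graph import PLUS, AssemblyGraph, Node


def make_graph(nodes, edges=()):
    """nodes: list of (id, length[, coverage]); edges: ((a, oa), (b, ob))."""
    g = AssemblyGraph()
    for spec in nodes:
        nid, length = spec[0], spec[1]
        cov = spec[2] if len(spec) > 2 else 30.0
        g.add_node(Node(nid, length, cov))
    for a, b in edges:
        g.add_edge(a, b)
    return g


def chain_graph(ids, length=300_000, coverage=30.0):
    g = make_graph([(i, length, coverage) for i in ids])
    for a, b in zip(ids, ids[1:]):
        g.add_edge((a, PLUS), (b, PLUS))
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
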