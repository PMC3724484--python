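import io

import numpy as np
import pytest

from bmfcluster.graph_io import ComplexSet, read_edge_list


@pytest.fixture
def running_ref() -> ComplexSet:
    """Reference with an overlap at 'c': R1={a,b,c}, R2={c,d}."""
    return ComplexSet.from_sets([{"a", "b", "c"}, {"c", "d"}], names=["R1", "R2"])


@pytest.fixture
def running_pred() -> ComplexSet:
    """Prediction partition P1={a,b}, P2={c,d}."""
    return ComplexSet.from_sets([{"a", "b"}, {"c", "d"}], names=["P1", "P2"])


@pytest.fixture
def two_triangles():
    return read_edge_list(io.StringIO("a b\nb c\nc a\nd e\ne f\nf d\n"))


@pytest.fixture
def two_clique_graph():
    """4 nodes, two disjoint 2-cliques (edges a-b and c-d)."""
    adj = np.zeros((4, 4), dtype=np.int8)
    adj[0, 1] = adj[1, 0] = 1
    adj[2, 3] = adj[3, 2] = 1
    return adj
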