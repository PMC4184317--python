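import itertools

import pytest

from fi_netkit.io import FINetwork


@pytest.fixture
def clique_pair() -> FINetwork:
    """Two 5-cliques joined by a single bridge edge."""
    net = FINetwork()
    c1 = [f"A{i}" for i in range(5)]
    c2 = [f"B{i}" for i in range(5)]
    for grp in (c1, c2):
        for a, b in itertools.combinations(grp, 2):
            net.add_edge(a, b)
    net.add_edge(c1[0], c2[0])
    return net


@pytest.fixture
def small_graph_family():
    """Fixed family of graphs with <= 10 nodes for enumeration oracles."""
    import networkx as nx

    graphs = [
        nx.path_graph(6),
        nx.cycle_graph(8),
        nx.complete_graph(5),
        nx.barbell_graph(4, 1),
        nx.star_graph(7),
        nx.gnp_random_graph(9, 0.35, seed=11),
        nx.gnp_random_graph(10, 0.3, seed=23),
        nx.gnp_random_graph(8, 0.5, seed=7),
    ]
    out = []
    for g in graphs:
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        out.append(nx.relabel_nodes(g, {n: f"G{n:02d}" for n in g.nodes}))
    return out
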