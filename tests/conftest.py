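import networkx as nx
import pytest

from orthokit.orthogroups import SimilarityGraph


def graph_from_edges(nodes, edges):
    """Build a SimilarityGraph directly.

    ``nodes``: {protein: species}; ``edges``: [(u, v, weight), ...].
    """
    g = nx.Graph()
    for pid, sp in nodes.items():
        g.add_node(pid, species=sp)
    for u, v, w in edges:
        cat = "intra" if nodes[u] == nodes[v] else "inter"
        g.add_edge(u, v, weight=w, category=cat)
    return SimilarityGraph(g)


@pytest.fixture
def make_graph():
    return graph_from_edges
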