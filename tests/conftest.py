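from __future__ import annotations

import networkx as nx
import pytest

from allomod.synth import SynthSpec, generate


def graph_from_edges(edges, name="g") -> nx.Graph:
    g = nx.Graph(name=name)
    g.add_edges_from(edges)
    return g


def clique(nodes, name="g") -> nx.Graph:
    g = nx.complete_graph(len(nodes))
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    g.graph["name"] = name
    return g


@pytest.fixture(scope="session")
def synth_default():
    """The default synthetic study: 1 vehicle + 3 compounds, seed 1."""
    return generate(SynthSpec(seed=1))


@pytest.fixture()
def triangle():
    return graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")], name="tri")


@pytest.fixture()
def four_clique_pendant():
    """4-clique abcd with pendant p attached to a."""
    g = clique(list("abcd"), name="k4p")
    g.add_edge("a", "p")
    return g
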