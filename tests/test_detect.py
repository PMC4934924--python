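"""Module detection: MCODE, Markov clustering, affinity propagation."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allomod.detect import (
    MCODE,
    GraphAffinityPropagation,
    MarkovClustering,
    ParameterGrid,
    affinity_propagation,
    default_grids,
    filter_modules,
    mcl,
    mcode,
    parameter_sweep,
)
from allomod.modules import ModularDecomposition, Module
from conftest import clique, graph_from_edges


def densest_subgraph_oracle(g: nx.Graph, min_nodes: int = 3):
    """Brute force: the maximum-density induced subgraph with >= min_nodes.

    Ties break toward more nodes, then the lexicographically smallest node
    tuple.  Exhaustive over all node subsets; only usable for tiny graphs.
    """
    best = None
    nodes = sorted(g.nodes())
    for r in range(min_nodes, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = g.subgraph(subset)
            n = len(subset)
            density = 2 * sub.number_of_edges() / (n * (n - 1))
            key = (density, n, tuple(reversed(subset)))
            if best is None or key > best[0]:
                best = (key, set(subset))
    return best[1]


class TestMCODE:
    def test_clique_with_pendant_haircut(self, four_clique_pendant):
        dec = mcode(four_clique_pendant, haircut=True)
        assert [sorted(m.nodes) for m in dec.modules] == [["a", "b", "c", "d"]]
        assert dec.modules[0].score == pytest.approx(4.0)  # density 1 x 4 nodes

    def test_edgeless_graph(self):
        g = nx.Graph(name="empty")
        g.add_nodes_from("abc")
        assert mcode(g).modules == []

    def test_two_disjoint_5cliques_equal_scores(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, str)
        dec = mcode(g)
        assert len(dec.modules) == 2
        assert all(m.size == 5 for m in dec.modules)
        assert dec.modules[0].score == pytest.approx(dec.modules[1].score)

    @pytest.mark.parametrize(
        "graph_builder",
        [
            # unique densest clique plus sparse appendage, <=7 nodes each
            lambda: graph_from_edges(
                list(itertools.combinations("abcd", 2)) + [("a", "p")]
            ),
            lambda: graph_from_edges(
                list(itertools.combinations("abcde", 2)) + [("a", "x"), ("x", "y")]
            ),
            lambda: graph_from_edges(
                list(itertools.combinations("abcd", 2)) + [("d", "e"), ("d", "f"), ("e", "f")]
            ),
            lambda: graph_from_edges(
                list(itertools.combinations("abcde", 2))
                + list(itertools.combinations("xyz", 2))
            ),
            lambda: graph_from_edges(
                list(itertools.combinations("abcdef", 2)) + [("a", "p")]
            ),
        ],
        ids=["k4+pendant", "k5+path2", "k4+shared-triangle", "k5|k3", "k6+pendant"],
    )
    def test_top_module_matches_densest_subgraph_oracle(self, graph_builder):
        g = graph_builder()
        g.graph["name"] = "oracle"
        dec = mcode(g, haircut=True)
        assert dec.modules, "expected at least one module"
        assert set(dec.modules[0].nodes) == densest_subgraph_oracle(g)

    def test_modules_are_induced_and_contain_kcore(self):
        g = nx.relabel_nodes(nx.powerlaw_cluster_graph(40, 3, 0.6, seed=5), str)
        g.graph["name"] = "plc"
        for m in mcode(g).modules:
            sub = g.subgraph(m.nodes)
            assert frozenset(map(frozenset, sub.edges())) == frozenset(map(frozenset, m.edges))
            assert max(nx.core_number(sub).values()) >= 2

    def test_deterministic(self):
        g = nx.relabel_nodes(nx.powerlaw_cluster_graph(30, 3, 0.5, seed=2), str)
        a = mcode(g)
        b = mcode(g)
        assert [m.nodes for m in a.modules] == [m.nodes for m in b.modules]

    def test_fluff_adds_dense_boundary(self):
        # pendant p's closed neighborhood a-p plus a's clique edges is dense
        g = clique(list("abcd"))
        g.add_edge("a", "p")
        dec = mcode(g, haircut=False, fluff=True, fluff_density=0.1)
        assert "p" in dec.modules[0].nodes

    def test_disjoint_union_is_union_of_components(self):
        g1 = clique(list("abcd"))
        g1.add_edge("a", "p")
        g2 = clique(list("wxyz"))
        both = nx.compose(g1, g2)
        got = {m.nodes for m in mcode(both).modules}
        expected = {m.nodes for m in mcode(g1).modules} | {m.nodes for m in mcode(g2).modules}
        assert got == expected


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        dec = mcl(g, inflation=2.0)
        assert {frozenset(m.nodes) for m in dec.modules} == {frozenset("abc"), frozenset("xyz")}

    def test_single_edge_one_cluster(self):
        dec = mcl(graph_from_edges([("a", "b")]), inflation=2.0)
        assert [sorted(m.nodes) for m in dec.modules] == [["a", "b"]]

    def test_barbell_matches_modularity_oracle(self):
        left, right = list("abcd"), list("wxyz")
        g = nx.compose(clique(left), clique(right))
        g.add_edge("d", "w")
        dec = mcl(g, inflation=2.0)
        got = {frozenset(m.nodes) for m in dec.modules}
        # exhaustive bipartition modularity maximum as independent oracle
        nodes = sorted(g.nodes())
        best, best_q = None, -np.inf
        for r in range(1, len(nodes) // 2 + 1):
            for part in itertools.combinations(nodes, r):
                q = nx.algorithms.community.modularity(
                    g, [set(part), set(nodes) - set(part)]
                )
                if q > best_q:
                    best, best_q = {frozenset(part), frozenset(set(nodes) - set(part))}, q
        assert got == best == {frozenset(left), frozenset(right)}

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl(graph_from_edges([("a", "b")]), inflation=1.0)

    def test_partitions_node_set(self):
        g = nx.relabel_nodes(nx.erdos_renyi_graph(25, 0.15, seed=3), str)
        dec = mcl(g, inflation=2.0)
        assert dec.is_partition_of(g.nodes())

    def test_disjoint_union_is_union_of_components(self):
        g1 = clique(list("abc"))
        g2 = clique(list("wxyz"))
        both = nx.compose(g1, g2)
        got = {frozenset(m.nodes) for m in mcl(both, inflation=2.0).modules}
        expected = {frozenset(m.nodes) for m in mcl(g1, inflation=2.0).modules} | {
            frozenset(m.nodes) for m in mcl(g2, inflation=2.0).modules
        }
        assert got == expected


class TestAffinityPropagation:
    def test_two_blocks_match_exhaustive_exemplar_oracle(self):
        n = 6
        sim = np.zeros((n, n))
        sim[:3, :3] = 1.0
        sim[3:, 3:] = 1.0
        pref = 0.5
        dec = affinity_propagation(sim, preference=pref)
        got = {frozenset(m.nodes) for m in dec.modules}
        assert got == {frozenset({"0", "1", "2"}), frozenset({"3", "4", "5"})}
        # oracle: exemplar subset maximizing net similarity
        best, best_score = None, -np.inf
        for r in range(1, n + 1):
            for ex in itertools.combinations(range(n), r):
                score = r * pref + sum(
                    max(sim[i, e] for e in ex) for i in range(n) if i not in ex
                )
                if score > best_score:
                    best, best_score = ex, score
        blocks = {frozenset(range(3)), frozenset(range(3, 6))}
        assert {frozenset({e}) | {i for i in range(n) if sim[i, e] == 1} for e in best} == blocks

    def test_single_point_is_own_exemplar(self):
        dec = affinity_propagation(np.array([[0.0]]), preference=0.5)
        assert [sorted(m.nodes) for m in dec.modules] == [["0"]]

    def test_uniform_similarity_high_preference_gives_singletons(self):
        sim = np.full((5, 5), 0.3)
        dec = affinity_propagation(sim, preference=100.0)
        assert all(m.size == 1 for m in dec.modules)
        assert len(dec.modules) == 5

    def test_partitions_graph_nodes(self):
        g = nx.relabel_nodes(nx.erdos_renyi_graph(15, 0.3, seed=4), str)
        dec = GraphAffinityPropagation(preference=0.5).fit_predict(g)
        assert dec.is_partition_of(g.nodes())

    def test_asymmetric_similarity_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            affinity_propagation(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestFilterModules:
    def _dec(self, sizes):
        mods = [
            Module(f"M{i}", frozenset(f"n{i}_{j}" for j in range(s)), frozenset())
            for i, s in enumerate(sizes)
        ]
        return ModularDecomposition(mods, "mcode")

    @pytest.mark.parametrize(
        "sizes, expected",
        [([5, 3, 2, 1], [5, 3]), ([4, 3, 3], [4, 3, 3]), ([2, 2], [])],
    )
    def test_size_filter(self, sizes, expected):
        out = filter_modules(self._dec(sizes), min_nodes=3)
        assert [m.size for m in out.modules] == expected


class TestParameterSweep:
    def test_stated_grid_sizes(self):
        grids = default_grids()
        assert len(grids["mcl"]) == 8  # inflation 1.5..5.0 step 0.5
        assert len(grids["ap"]) == 10  # preference 0.1..1.0 step 0.1
        assert len(grids["mcode"]) == 16  # haircut x fluff x 4 depths

    def test_one_decomposition_per_record(self):
        g = clique(list("abcde"))
        decs = parameter_sweep(g, default_grids()["mcl"])
        assert len(decs) == 8
        assert [d.params["inflation"] for d in decs] == [1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]

    def test_singleton_grid(self):
        g = clique(list("abc"))
        decs = parameter_sweep(g, ParameterGrid("mcl", [{"inflation": 2.0}]))
        assert len(decs) == 1

    def test_failure_recorded_not_raised(self):
        g = clique(list("abc"))
        decs = parameter_sweep(g, ParameterGrid("mcl", [{"inflation": 0.5}]))
        assert len(decs) == 1
        assert decs[0].modules == []
        assert any("failed" in w for w in decs[0].warnings)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid("mcl", [])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_mcl_and_ap_partition_random_graphs(seed):
    g = nx.relabel_nodes(nx.gnp_random_graph(12, 0.3, seed=seed), str)
    assert MarkovClustering(inflation=2.0).fit_predict(g).is_partition_of(g.nodes())
    assert GraphAffinityPropagation(preference=0.5).fit_predict(g).is_partition_of(g.nodes())
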