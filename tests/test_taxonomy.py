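"""Allosteric-type classification, watershed search, gradients, regressions."""

from __future__ import annotations

import math

import pytest

from allomod.modules import ModularDecomposition, module_from_nodes
from allomod.siminef import ThresholdLadder, pairwise_similarity
from allomod.taxonomy import (
    classify,
    find_wam,
    function_topology_correlation,
    gradient_counts,
    nonoverlap_regression,
    overlap_graph,
    pearson_correlation,
)
from conftest import clique


def make_dec(condition, node_lists):
    mods = []
    for i, nodes in enumerate(node_lists):
        g = clique(list(nodes))
        mods.append(module_from_nodes(g, list(nodes), f"M{i + 1}", condition=condition))
    return ModularDecomposition(mods, "mcode", network_ref=condition)


def all_sims(decs, functions=None):
    sims = []
    for i, a in enumerate(decs):
        for b in decs[i + 1 :]:
            sims.extend(pairwise_similarity(a, b, functions))
    return sims


@pytest.fixture()
def two_condition_world():
    """Vehicle with 3 modules; compound with an identical, a disjoint, a partial."""
    vehicle = make_dec("v", ["abcd", "efgh", "ijkl"])
    compound = make_dec("c", ["abcd", "wxyz", "ijmn"])
    funcs = {}
    for dec in (vehicle, compound):
        for m in dec.modules:
            funcs[(m.condition, m.id)] = frozenset({f"T_{min(m.nodes)}"})
    return vehicle, compound, all_sims([vehicle, compound], funcs)


class TestClassify:
    def test_identical_pair_is_cam(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        records = classify(vehicle, [compound], sims)
        cams = [r for r in records if r.am_type == "CAM"]
        assert len(cams) == 1
        assert set(cams[0].members) == {("v", "M1"), ("c", "M1")}
        assert all(e.components() == (1.0, 1.0, 1.0) for e in cams[0].evidence)

    def test_unmatched_compound_module_is_gam_at_every_level(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        records = classify(vehicle, [compound], sims)
        gam_levels = {r.level for r in records if r.am_type == "GAM" and r.members == (("c", "M2"),)}
        assert gam_levels == set(ThresholdLadder().levels)

    def test_unmatched_vehicle_module_is_dam_at_every_level(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        records = classify(vehicle, [compound], sims)
        dam_levels = {r.level for r in records if r.am_type == "DAM" and r.members == (("v", "M2"),)}
        assert dam_levels == set(ThresholdLadder().levels)

    def test_partial_overlap_pair_is_am(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        records = classify(vehicle, [compound], sims)
        ams = [r for r in records if r.am_type == "AM"]
        assert any(set(r.members) == {("v", "M3"), ("c", "M3")} for r in ams)

    def test_missing_similarity_record_raises(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        with pytest.raises(KeyError, match="no similarity record"):
            classify(vehicle, [compound], sims[:-1])

    def test_synthetic_counts_recovered(self, synth_default):
        from allomod.pipeline import analyze_conditions
        from allomod.detect import default_grids

        res = synth_default
        out = analyze_conditions(
            res.target_networks,
            vehicle="V",
            annotations=res.annotations,
            grids={"mcode": default_grids()["mcode"]},
        )
        cams = [r for r in out.am_records if r.am_type == "CAM"]
        gams_l1 = [r for r in out.am_records if r.am_type == "GAM" and r.level == 1.0]
        dams_l1 = [r for r in out.am_records if r.am_type == "DAM" and r.level == 1.0]
        gt = res.ground_truth
        n_cam_families = sum(1 for lab in gt.family_labels.values() if lab == "CAM")
        n_gam_families = sum(1 for lab in gt.family_labels.values() if lab == "GAM")
        n_dam_families = sum(1 for lab in gt.family_labels.values() if lab == "DAM")
        assert len(cams) == n_cam_families == 2
        assert len(gams_l1) == n_gam_families == 3
        assert len(dams_l1) == n_dam_families == 1


class TestOverlapGraph:
    def test_any_vs_all_rule(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        decs = [vehicle, compound]
        pair = (("v", "M3"), ("c", "M3"))  # nodes 4/6 overlap but functions differ
        any_g = overlap_graph(decs, sims, 50, rule="any_of_three")
        all_g = overlap_graph(decs, sims, 50, rule="all_of_three")
        assert any_g.has_edge(*pair)
        assert not all_g.has_edge(*pair)

    def test_all_subset_of_any_at_every_level(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        decs = [vehicle, compound]
        for level in ThresholdLadder().levels:
            all_e = set(overlap_graph(decs, sims, level, "all_of_three").edges())
            any_e = set(overlap_graph(decs, sims, level, "any_of_three").edges())
            assert all_e <= any_e

    def test_no_within_condition_links(self, two_condition_world):
        vehicle, compound, sims = two_condition_world
        g = overlap_graph([vehicle, compound], sims, 1, "any_of_three")
        assert all(a[0] != b[0] for a, b in g.edges())

    def test_identical_decompositions_fully_linked(self):
        a = make_dec("v", ["abc", "def"])
        b = make_dec("c", ["abc", "def"])
        funcs = {(m.condition, m.id): frozenset({"T"}) for d in (a, b) for m in d.modules}
        g = overlap_graph([a, b], all_sims([a, b], funcs), 50, "all_of_three")
        assert g.has_edge(("v", "M1"), ("c", "M1"))
        assert g.has_edge(("v", "M2"), ("c", "M2"))


class TestFindWam:
    def _four_condition_world(self, shared_fraction="high"):
        # one module per condition built around a common core
        core = list("abcdef")
        variants = {
            "v": core + ["v1", "v2"],
            "c1": core + ["x1", "x2"],
            "c2": core + ["y1", "y2"],
            "c3": core + ["z1", "z2"],
        }
        decs = [make_dec(cond, ["".join([])] and [variants[cond]]) for cond in variants]
        funcs = {(d.network_ref, "M1"): frozenset({"T"}) for d in decs}
        return decs, all_sims(decs, funcs)

    def test_spanning_tuple_found_at_highest_qualifying_level(self):
        decs, sims = self._four_condition_world()
        # core 6 of 8 nodes: s_n = 6/10 = 0.6; s_e = C(6,2)/(2*C(8,2)-C(6,2)) ~ 0.366
        wams = find_wam(decs, sims, ThresholdLadder())
        assert len(wams) == 1
        assert wams[0].level == 25.0
        assert {ref[0] for ref in wams[0].members} == {"v", "c1", "c2", "c3"}

    def test_level_is_maximal(self):
        decs, sims = self._four_condition_world()
        wams = find_wam(decs, sims, ThresholdLadder())
        level = wams[0].level
        for higher in [lv for lv in ThresholdLadder().non_terminal() if lv > level]:
            g = overlap_graph(decs, sims, higher, "all_of_three")
            import networkx as nx

            spanning = [
                c for c in nx.connected_components(g) if {r[0] for r in c} == {"v", "c1", "c2", "c3"}
            ]
            assert spanning == []

    def test_no_overlap_returns_empty(self):
        a = make_dec("v", ["abc"])
        b = make_dec("c", ["xyz"])
        assert find_wam([a, b], all_sims([a, b])) == []

    def test_planted_wam_recovered(self, synth_default):
        from allomod.pipeline import analyze_conditions
        from allomod.detect import default_grids

        res = synth_default
        out = analyze_conditions(
            res.target_networks,
            vehicle="V",
            annotations=res.annotations,
            grids={"mcode": default_grids()["mcode"]},
        )
        gt = res.ground_truth
        assert out.wam_records, "expected a watershed module"
        wam = out.wam_records[0]
        assert wam.level == gt.wam_level
        planted_nodes = {
            frozenset(gt.memberships[c][gt.wam_family]) for c in (gt.vehicle, *gt.compounds)
        }
        detected_nodes = {
            frozenset(
                next(m.nodes for m in out.decompositions[cond].modules if m.id == mid)
            )
            for cond, mid in wam.members
        }
        assert detected_nodes == planted_nodes


class TestGradientCounts:
    def test_identical_decompositions_no_nonoverlap_below_terminal(self):
        a = make_dec("v", ["abc", "def"])
        b = make_dec("c", ["abc", "def"])
        funcs = {(m.condition, m.id): frozenset({"T"}) for d in (a, b) for m in d.modules}
        gc = gradient_counts([a, b], all_sims([a, b], funcs))
        for level, per in gc.counts.items():
            if level < 100:
                assert per["v"] == (2, 0) and per["c"] == (2, 0)

    def test_disjoint_decompositions_no_overlap_anywhere(self):
        a = make_dec("v", ["abc"])
        b = make_dec("c", ["xyz"])
        gc = gradient_counts([a, b], all_sims([a, b]))
        for per in gc.counts.values():
            assert per["v"] == (0, 1) and per["c"] == (0, 1)

    def test_counts_conserve_totals_and_monotone(self, synth_default):
        from allomod.pipeline import analyze_conditions
        from allomod.detect import default_grids

        res = synth_default
        out = analyze_conditions(
            res.target_networks, vehicle="V", annotations=res.annotations,
            grids={"mcode": default_grids()["mcode"]},
        )
        gc = out.gradient
        levels = sorted(gc.counts)
        for cond, total in gc.module_totals.items():
            prev = math.inf
            for level in levels:
                o, n = gc.counts[level][cond]
                assert o + n == total
                assert o <= prev  # overlap count non-increasing in k
                prev = o


class TestRegressions:
    def _counts(self, levels, nonoverlap):
        from allomod.taxonomy import GradientCounts

        return GradientCounts(
            counts={lv: {"v": (0, n)} for lv, n in zip(levels, nonoverlap)},
            module_totals={"v": max(nonoverlap)},
        )

    def test_exact_line(self):
        slope, stderr, _ = nonoverlap_regression(self._counts([1, 2, 3], [1, 2, 3]), "v")
        assert slope == pytest.approx(1.0)
        assert stderr == pytest.approx(0.0, abs=1e-12)

    def test_constant_counts(self):
        slope, _, _ = nonoverlap_regression(self._counts([1, 2, 3, 4], [5, 5, 5, 5]), "v")
        assert slope == pytest.approx(0.0)

    def test_hand_computed_slope(self):
        slope, _, _ = nonoverlap_regression(self._counts([1, 2, 3], [2, 2, 5]), "v")
        assert slope == pytest.approx(1.5)

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            nonoverlap_regression(self._counts([1, 2], [1, 2]), "v")


class TestCorrelation:
    def test_perfect_linear(self):
        assert pearson_correlation([(1, 2), (2, 4), (3, 6)])["r"] == pytest.approx(1.0)

    def test_anti_linear(self):
        assert pearson_correlation([(1, 6), (2, 4), (3, 2)])["r"] == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        rec = pearson_correlation([(1, 2), (2, 1), (3, 4), (4, 3)])
        assert rec["r"] == pytest.approx(0.6)

    def test_zero_variance_flagged(self):
        rec = pearson_correlation([(1, 5), (2, 5), (3, 5)])
        assert not rec["defined"]

    def test_function_topology_record(self):
        g1 = clique(list("abc"))
        import networkx as nx

        star = nx.Graph([("h", "x"), ("h", "y"), ("h", "z")])
        mods = [
            module_from_nodes(g1, "abc", "M1"),
            module_from_nodes(star, "hxyz", "M2"),
        ]
        funcs = {"M1": frozenset({"T1"}), "M2": frozenset({"T1", "T2", "T3"})}
        rec = function_topology_correlation(mods, funcs)
        assert rec["defined"] and -1.0 <= rec["r"] <= 1.0 and rec["n"] == 7
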