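"""Synthetic multi-condition networks with known allosteric-module ground truth.

The generator emulates the study design the pipeline targets: a baseline
("vehicle") condition and several compound conditions, each with a
condition-specific target network carved out of one global interaction
network by differential expression.  Modules are planted as dense
planted-partition blocks whose fate per compound condition is scripted:

* ``conserve`` — identical node/edge set in the compound condition;
* ``delete``  — absent from the compound condition;
* ``generate`` — absent from the vehicle, present in the compound;
* ``rewire(f)`` — a fraction *f* of the module's nodes replaced by fresh
  genes (the same replacement in every rewiring compound), yielding a
  planned node Jaccard of (1-f)n / (1+f)n against the vehicle copy.

Expression values are generated post hoc to satisfy the differential rule
(planted-module genes score above the threshold in the conditions where
their module exists; background genes stay below), and one annotation term
per planted family covers its gene universe, so enrichment recovers the
planted functions.  All bookkeeping (planned overlaps, planted
CAM/GAM/DAM/WAM labels and the planted watershed level) is recorded by set
arithmetic at generation time, independent of any detection run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .network import canonical_edge
from .siminef import ThresholdLadder

__all__ = ["PlantedModule", "SynthSpec", "GroundTruth", "SynthResult", "generate", "watershed_gene_sets"]


@dataclass(frozen=True)
class PlantedModule:
    """One planted module family and its fate in each compound condition."""

    name: str
    size: int
    in_vehicle: bool
    actions: dict[str, object]  # compound -> "conserve" | "delete" | "generate" | ("rewire", f)

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("planted modules need at least 3 nodes")
        for cond, action in self.actions.items():
            if isinstance(action, tuple):
                kind, frac = action
                if kind != "rewire" or not 0.0 <= frac <= 1.0:
                    raise ValueError(f"bad action {action!r} for {self.name} in {cond}")
            elif action not in ("conserve", "delete", "generate"):
                raise ValueError(f"bad action {action!r} for {self.name} in {cond}")


def _default_plan(compounds: tuple[str, ...]) -> tuple[PlantedModule, ...]:
    """The default study plan: 2 conserved, 3 generated, 1 deleted, 1 rewired.

    Conserved families deliberately do not span every compound, so the only
    family overlapping across *all* conditions is the partially rewired one
    — the planted watershed.
    """
    c1, c2, c3 = compounds
    return (
        PlantedModule("F1", 6, True, {c1: "conserve", c2: "delete", c3: "delete"}),
        PlantedModule("F2", 5, True, {c1: "delete", c2: "conserve", c3: "conserve"}),
        PlantedModule("F3", 6, False, {c1: "generate", c2: "delete", c3: "delete"}),
        PlantedModule("F4", 5, False, {c1: "delete", c2: "generate", c3: "delete"}),
        PlantedModule("F5", 7, False, {c1: "delete", c2: "delete", c3: "generate"}),
        PlantedModule("F6", 5, True, {c1: "delete", c2: "delete", c3: "delete"}),
        PlantedModule(
            "F7", 8, True, {c1: ("rewire", 0.25), c2: ("rewire", 0.25), c3: ("rewire", 0.25)}
        ),
    )


@dataclass
class SynthSpec:
    """Generator configuration; the defaults are the study conditions.

    ``p_in`` is the within-module edge probability (1.0 plants cliques,
    which matches the clique-like complexes the detector is tuned for);
    ``p_out`` adds sparse background edges between genes of different
    families and background genes.  ``diff_value`` is the expression score
    given to module genes in conditions where their module exists — above
    the differential threshold of 1 — while background genes draw from
    U(-background_scale, background_scale).
    """

    seed: int
    n_background_genes: int = 120
    vehicle: str = "V"
    compounds: tuple[str, ...] = ("C1", "C2", "C3")
    plan: tuple[PlantedModule, ...] | None = None
    p_in: float = 1.0
    p_out: float = 0.0
    diff_value: float = 2.0
    background_scale: float = 0.8
    noise_genes_per_term: int = 2
    ladder: ThresholdLadder = field(default_factory=ThresholdLadder)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.plan is None:
            if len(self.compounds) != 3:
                raise ValueError("the default plan needs exactly 3 compound conditions")
            self.plan = _default_plan(self.compounds)


@dataclass
class GroundTruth:
    """Planted memberships, planned overlaps, and family labels."""

    vehicle: str
    compounds: tuple[str, ...]
    memberships: dict[str, dict[str, frozenset[str]]]  # condition -> family -> nodes
    family_labels: dict[str, str]  # family -> CAM | GAM | DAM | WAM | AM
    planned_overlaps: dict[tuple[str, str, str], dict[str, float]]  # (family, cond_a, cond_b)
    wam_family: str | None
    wam_level: float | None


@dataclass
class SynthResult:
    global_network: nx.Graph
    target_networks: dict[str, nx.Graph]
    expression: pd.DataFrame
    annotations: AnnotationSet
    ground_truth: GroundTruth


def _family_edges(nodes: list[str], p_in: float, rng: np.random.Generator) -> set[tuple[str, str]]:
    """Master edge set over a family's full gene universe.

    Sampled once per family so that every variant's induced edges are
    mutually consistent (conserved copies identical, rewired copies share
    the edges among shared nodes).  With p_in = 1 this is a clique; lower
    p_in rejects samples until the set stays connected on the universe.
    """
    for _ in range(200):
        edges = {
            canonical_edge(u, v)
            for i, u in enumerate(nodes)
            for v in nodes[i + 1 :]
            if p_in >= 1.0 or rng.random() < p_in
        }
        g = nx.Graph(edges)
        g.add_nodes_from(nodes)
        if nx.is_connected(g):
            return edges
    raise ValueError(f"could not sample a connected module at p_in={p_in}")


def generate(spec: SynthSpec) -> SynthResult:
    """Generate networks, expression, annotations and ground truth.

    Deterministic: the same spec (including seed) yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(spec.seed)
    conditions = (spec.vehicle, *spec.compounds)
    plan = spec.plan
    assert plan is not None

    # --- allocate gene IDs: family universes first, background after
    next_gene = 0

    def take(n: int) -> list[str]:
        nonlocal next_gene
        out = [f"g{next_gene + i:04d}" for i in range(n)]
        next_gene += n
        return out

    family_base: dict[str, list[str]] = {}
    family_repl: dict[str, list[str]] = {}
    for fam in plan:
        family_base[fam.name] = take(fam.size)
        n_repl = max(
            (
                math.ceil(action[1] * fam.size)
                for action in fam.actions.values()
                if isinstance(action, tuple)
            ),
            default=0,
        )
        family_repl[fam.name] = take(n_repl)
    background_genes = take(spec.n_background_genes)
    all_genes = [f"g{i:04d}" for i in range(next_gene)]
    total_module_genes = next_gene - spec.n_background_genes
    if total_module_genes > len(all_genes):
        raise ValueError("module sizes exceed the gene universe")

    # --- per-condition variant node sets
    memberships: dict[str, dict[str, frozenset[str]]] = {c: {} for c in conditions}
    for fam in plan:
        base = family_base[fam.name]
        if fam.in_vehicle:
            memberships[spec.vehicle][fam.name] = frozenset(base)
        for cond in spec.compounds:
            action = fam.actions.get(cond, "delete")
            if action == "delete":
                continue
            if action in ("conserve", "generate"):
                memberships[cond][fam.name] = frozenset(base)
            else:  # rewire
                _, frac = action
                n_repl = math.ceil(frac * fam.size)
                kept = base[: fam.size - n_repl]
                repl = family_repl[fam.name][:n_repl]
                memberships[cond][fam.name] = frozenset(kept + repl)

    # --- global network: family master edges restricted to realized variants,
    #     plus sparse background edges outside families
    family_universe = {
        fam.name: family_base[fam.name] + family_repl[fam.name] for fam in plan
    }
    master_edges = {
        fam.name: _family_edges(family_universe[fam.name], spec.p_in, rng) for fam in plan
    }
    global_net = nx.Graph(name="global")
    global_net.add_nodes_from(all_genes)
    for fam in plan:
        edges = master_edges[fam.name]
        for cond in conditions:
            nodes = memberships[cond].get(fam.name)
            if nodes is None:
                continue
            global_net.add_edges_from(
                (u, v) for u, v in edges if u in nodes and v in nodes
            )
    if spec.p_out > 0:
        in_family = {g: f for f, genes in family_universe.items() for g in genes}
        n = len(all_genes)
        for i in range(n):
            for j in range(i + 1, n):
                u, v = all_genes[i], all_genes[j]
                if in_family.get(u) is not None and in_family.get(u) == in_family.get(v):
                    continue  # within-family pairs are governed by p_in
                if rng.random() < spec.p_out:
                    global_net.add_edge(u, v)

    # --- expression: post hoc to match the differential rule
    values = rng.uniform(-spec.background_scale, spec.background_scale, size=(len(all_genes), len(conditions)))
    expr = pd.DataFrame(values, index=all_genes, columns=list(conditions))
    for cond in conditions:
        for nodes in memberships[cond].values():
            expr.loc[sorted(nodes), cond] = spec.diff_value

    # --- target networks, induced by each condition's differential genes
    target_networks: dict[str, nx.Graph] = {}
    for cond in conditions:
        diff = set(expr.index[expr[cond] > 1.0])
        sub = nx.Graph(global_net.subgraph(diff))
        sub.graph.clear()
        sub.graph["name"] = cond
        sub.graph["source_genes"] = diff
        target_networks[cond] = sub

    # --- annotations: one term per family over its gene universe plus noise
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for fam in plan:
        noise = [
            str(g)
            for g in rng.choice(background_genes, size=spec.noise_genes_per_term, replace=False)
        ]
        terms[f"T_{fam.name}"] = frozenset(family_universe[fam.name]) | frozenset(noise)
        descriptions[f"T_{fam.name}"] = f"planted term for family {fam.name}"
    annotations = AnnotationSet(
        terms=terms, background=frozenset(all_genes), descriptions=descriptions
    )

    ground_truth = _ground_truth(spec, memberships, master_edges)
    return SynthResult(
        global_network=global_net,
        target_networks=target_networks,
        expression=expr,
        annotations=annotations,
        ground_truth=ground_truth,
    )


def _ground_truth(
    spec: SynthSpec,
    memberships: dict[str, dict[str, frozenset[str]]],
    master_edges: dict[str, set[tuple[str, str]]],
) -> GroundTruth:
    conditions = (spec.vehicle, *spec.compounds)
    plan = spec.plan
    assert plan is not None
    labels: dict[str, str] = {}
    overlaps: dict[tuple[str, str, str], dict[str, float]] = {}
    wam_family: str | None = None
    wam_level: float | None = None

    for fam in plan:
        present = [c for c in conditions if fam.name in memberships[c]]
        in_vehicle = spec.vehicle in present
        in_compound = any(c in present for c in spec.compounds)
        conserved = any(fam.actions.get(c) == "conserve" for c in spec.compounds)
        rewired = any(isinstance(fam.actions.get(c), tuple) for c in spec.compounds)

        # planned pairwise overlaps by set arithmetic on the planted variants
        pair_min = 1.0
        for i, ca in enumerate(present):
            for cb in present[i + 1 :]:
                na, nb = memberships[ca][fam.name], memberships[cb][fam.name]
                ea = {e for e in master_edges[fam.name] if e[0] in na and e[1] in na}
                eb = {e for e in master_edges[fam.name] if e[0] in nb and e[1] in nb}
                s_n = len(na & nb) / len(na | nb)
                s_e = len(ea & eb) / len(ea | eb) if (ea | eb) else 0.0
                s_f = 1.0  # same planted term annotates every variant
                overlaps[(fam.name, ca, cb)] = {"s_n": s_n, "s_e": s_e, "s_f": s_f}
                pair_min = min(pair_min, s_n, s_e, s_f)

        if in_vehicle and conserved:
            labels[fam.name] = "CAM"
        elif not in_vehicle and in_compound:
            labels[fam.name] = "GAM"
        elif in_vehicle and not in_compound:
            labels[fam.name] = "DAM"
        elif in_vehicle and rewired:
            labels[fam.name] = "AM"
        else:
            labels[fam.name] = "AM"

        if set(present) == set(conditions) and 0.0 < pair_min < 1.0:
            level = 0.0
            for lv in spec.ladder.non_terminal():
                if pair_min > lv / 100.0:
                    level = lv
            if wam_level is None or level > wam_level:
                wam_family, wam_level = fam.name, level
                labels[fam.name] = "WAM"

    return GroundTruth(
        vehicle=spec.vehicle,
        compounds=spec.compounds,
        memberships=memberships,
        family_labels=labels,
        planned_overlaps=overlaps,
        wam_family=wam_family,
        wam_level=wam_level,
    )


def watershed_gene_sets() -> dict[str, frozenset[str]]:
    """Reference watershed-module gene sets (Entrez IDs) for worked examples.

    Taken from the motivating ischemic-mouse compound comparison (vehicle V
    versus baicalin BA, cholic acid CA and jasminoidin JA groups).

    ``AM_CA6``, ``AM_JA6`` and ``AM_V7`` list the same six genes; ``AM_BA10``
    lacks one of them.  ``AMW_BC_shared`` is the gene set common to the
    BA/CA watershed pair.
    """
    return {
        "AM_BA10": frozenset({"66467", "209357", "13872", "17420", "12572"}),
        "AM_CA6": frozenset({"12572", "13872", "14884", "209357", "66467", "17420"}),
        "AM_JA6": frozenset({"12572", "13872", "14884", "209357", "66467", "17420"}),
        "AM_V7": frozenset({"12572", "13872", "14884", "66467", "209357", "17420"}),
        "AM_BA49": frozenset({"54364", "74097", "117109", "67676"}),
        "AM_JA42": frozenset({"54364", "74097", "117109", "66161"}),
        "AMW_BC_shared": frozenset({"225887", "226646", "75406", "69372"}),
    }
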