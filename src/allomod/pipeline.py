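"""End-to-end orchestration: detect, select, enrich, compare, classify."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .detect import ParameterGrid, default_grids, filter_modules, parameter_sweep
from .enrichment import AnnotationSet, module_functions
from .entropy import select_min_entropy
from .modules import ModularDecomposition
from .siminef import ModuleRef, SimilarityRecord, ThresholdLadder, pairwise_similarity
from .taxonomy import AMRecord, GradientCounts, classify, find_wam, gradient_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "select_decomposition", "analyze_conditions"]


@dataclass
class PipelineResult:
    decompositions: dict[str, ModularDecomposition]
    selection_tables: dict[str, pd.DataFrame]
    functions: dict[ModuleRef, frozenset[str]]
    similarities: list[SimilarityRecord]
    am_records: list[AMRecord]
    wam_records: list[AMRecord]
    gradient: GradientCounts
    ladder: ThresholdLadder = field(default_factory=ThresholdLadder)


def select_decomposition(
    net: nx.Graph,
    grids: dict[str, ParameterGrid] | None = None,
    min_nodes: int = 3,
) -> tuple[ModularDecomposition, pd.DataFrame]:
    """Sweep all methods/parameters on one network, keep the minimum-entropy one.

    Every decomposition is filtered to modules with >= ``min_nodes`` nodes
    before scoring, matching the study's reporting filter.
    """
    grids = grids or default_grids()
    candidates: list[ModularDecomposition] = []
    for grid in grids.values():
        candidates.extend(
            filter_modules(dec, min_nodes) for dec in parameter_sweep(net, grid)
        )
    return select_min_entropy(candidates)


def analyze_conditions(
    target_networks: dict[str, nx.Graph],
    vehicle: str,
    annotations: AnnotationSet | None = None,
    grids: dict[str, ParameterGrid] | None = None,
    ladder: ThresholdLadder = ThresholdLadder(),
    alpha: float = 0.05,
    min_nodes: int = 3,
) -> PipelineResult:
    """Run the full comparison across one vehicle and >= 1 compound conditions.

    Per condition: parameter sweep, size filter, minimum-entropy selection.
    Then per-module significant-term sets (against the annotation background
    restricted to each network's genes), all cross-condition SimiNEF
    records, the five-type classification, the watershed search, and the
    overlap gradient.
    """
    if vehicle not in target_networks:
        raise KeyError(f"vehicle condition {vehicle!r} not among target networks")
    decomps: dict[str, ModularDecomposition] = {}
    tables: dict[str, pd.DataFrame] = {}
    for cond, net in target_networks.items():
        best, table = select_decomposition(net, grids=grids, min_nodes=min_nodes)
        decomps[cond] = best
        tables[cond] = table
        logger.info(
            "%s: selected %s with %d modules", cond, best.method, len(best.modules)
        )

    functions: dict[ModuleRef, frozenset[str]] = {}
    if annotations is not None:
        for cond, dec in decomps.items():
            ann = annotations.restricted_to(set(target_networks[cond].nodes()))
            per_id = module_functions(dec.modules, ann, alpha=alpha)
            for mid, terms in per_id.items():
                functions[(cond, mid)] = terms

    conds = list(decomps)
    sims: list[SimilarityRecord] = []
    for i, ca in enumerate(conds):
        for cb in conds[i + 1 :]:
            sims.extend(pairwise_similarity(decomps[ca], decomps[cb], functions))

    compounds = [decomps[c] for c in conds if c != vehicle]
    records = classify(decomps[vehicle], compounds, sims, ladder)
    wams = find_wam(list(decomps.values()), sims, ladder)
    grad = gradient_counts(list(decomps.values()), sims, ladder)
    return PipelineResult(
        decompositions=decomps,
        selection_tables=tables,
        functions=functions,
        similarities=sims,
        am_records=records,
        wam_records=wams,
        gradient=grad,
        ladder=ladder,
    )
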