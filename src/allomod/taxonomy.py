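"""Classification of modules into the five allosteric types.

Comparing one vehicle (baseline) condition against one or more compound
conditions, every module receives a disposition per similarity level:

* **AM** — a cross-condition pair with partial overlap (all three SimiNEF
  components strictly between 0 and 1);
* **CAM** (conserved) — a vehicle module with at least one compound module
  whose node, edge and function similarities all equal 1;
* **GAM** (generated) — a compound module with no vehicle counterpart at
  the operative level ("birth");
* **DAM** (disappeared) — a vehicle module with no counterpart in any
  compound condition at the operative level ("death");
* **WAM** (watershed) — the cross-condition module tuple that still forms a
  connected overlap component spanning every condition at the highest
  non-terminal ladder level, marking the demarcation between shared and
  divergent mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .modules import Module, ModularDecomposition
from .siminef import (
    ModuleRef,
    SimilarityRecord,
    ThresholdLadder,
    connecting_percentage,
    snef_exceeds,
)

__all__ = [
    "AMRecord",
    "GradientCounts",
    "SimilarityIndex",
    "classify",
    "find_wam",
    "overlap_graph",
    "gradient_counts",
    "nonoverlap_regression",
    "pearson_correlation",
    "function_topology_correlation",
]


@dataclass(frozen=True)
class AMRecord:
    """One taxonomy call: a module (or tuple) labeled with its type and level."""

    am_type: str  # AM | CAM | GAM | DAM | WAM
    members: tuple[ModuleRef, ...]
    level: float | None
    evidence: tuple[SimilarityRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.am_type not in ("AM", "CAM", "GAM", "DAM", "WAM"):
            raise ValueError(f"unknown allosteric type {self.am_type!r}")


@dataclass
class GradientCounts:
    """Per ladder level and condition: (overlapping, non-overlapping) counts."""

    counts: dict[float, dict[str, tuple[int, int]]]
    module_totals: dict[str, int]


class SimilarityIndex:
    """Symmetric lookup of SimilarityRecords by unordered module-ref pair."""

    def __init__(self, records: Iterable[SimilarityRecord]):
        self._by_pair: dict[frozenset[ModuleRef], SimilarityRecord] = {}
        for r in records:
            self._by_pair[frozenset((r.module_a, r.module_b))] = r

    def get(self, a: ModuleRef, b: ModuleRef) -> SimilarityRecord:
        try:
            return self._by_pair[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no similarity record for pair {a} vs {b}") from None

    def __len__(self) -> int:
        return len(self._by_pair)


def _refs(dec: ModularDecomposition) -> list[ModuleRef]:
    return [(m.condition, m.id) for m in dec.modules]


def _qualifies(rec: SimilarityRecord, level: float, terminal: float = 100.0) -> bool:
    return snef_exceeds(rec, level, terminal=level >= terminal)


def classify(
    vehicle: ModularDecomposition,
    compounds: Sequence[ModularDecomposition],
    sims: Iterable[SimilarityRecord],
    ladder: ThresholdLadder = ThresholdLadder(),
) -> list[AMRecord]:
    """Label modules as AM / CAM / GAM / DAM across the threshold ladder.

    Requires a similarity record for every cross-condition module pair
    (vehicle x compound and compound x compound); a missing pair raises,
    naming it.  CAMs are emitted once (terminal level), grouping a vehicle
    module with every compound module identical to it.  GAMs and DAMs are
    emitted per ladder level.  AM calls cover cross pairs with partial
    overlap — every component positive and at least one below 1 (the
    smallest component strictly inside (0, 1)); each carries the highest
    non-terminal ladder level it qualifies at (0.0 if below the lowest
    rung).
    """
    index = SimilarityIndex(sims)
    v_refs = _refs(vehicle)
    comp_refs = {dec.network_ref: _refs(dec) for dec in compounds}
    all_decs = [vehicle, *compounds]
    # validate completeness across every cross-condition pair
    for i, da in enumerate(all_decs):
        for db in all_decs[i + 1 :]:
            for ra in _refs(da):
                for rb in _refs(db):
                    index.get(ra, rb)

    records: list[AMRecord] = []

    # CAM: vehicle module with >=1 identical compound module
    for vref in v_refs:
        identical: list[ModuleRef] = []
        evidence: list[SimilarityRecord] = []
        for refs in comp_refs.values():
            for cref in refs:
                rec = index.get(vref, cref)
                if _qualifies(rec, 100.0):
                    identical.append(cref)
                    evidence.append(rec)
        if identical:
            records.append(
                AMRecord("CAM", (vref, *identical), level=100.0, evidence=tuple(evidence))
            )

    # GAM / DAM per ladder level
    for level in ladder.levels:
        for cond, refs in comp_refs.items():
            for cref in refs:
                if not any(_qualifies(index.get(cref, vref), level) for vref in v_refs):
                    records.append(AMRecord("GAM", (cref,), level=level))
        for vref in v_refs:
            counterpart = any(
                _qualifies(index.get(vref, cref), level)
                for refs in comp_refs.values()
                for cref in refs
            )
            if not counterpart:
                records.append(AMRecord("DAM", (vref,), level=level))

    # AM: cross pairs with strictly partial overlap in every component
    for i, da in enumerate(all_decs):
        for db in all_decs[i + 1 :]:
            for ra in _refs(da):
                for rb in _refs(db):
                    rec = index.get(ra, rb)
                    low = min(rec.components())
                    if 0.0 < low < 1.0:
                        level = 0.0
                        for lv in ladder.non_terminal():
                            if _qualifies(rec, lv):
                                level = lv
                        records.append(
                            AMRecord("AM", (ra, rb), level=level, evidence=(rec,))
                        )
    return records


def overlap_graph(
    decomps: Sequence[ModularDecomposition],
    sims: Iterable[SimilarityRecord] | SimilarityIndex,
    k: float,
    rule: str = "all_of_three",
) -> nx.Graph:
    """Multipartite module-overlap graph at threshold level ``k`` (percent).

    Vertices are (condition, module id) pairs; cross-condition pairs are
    linked when they meet the connect rule: ``all_of_three`` requires every
    SimiNEF component to exceed k (equal 1 at the terminal level),
    ``any_of_three`` requires at least one.  Within-condition links never
    occur.
    """
    if rule not in ("all_of_three", "any_of_three"):
        raise ValueError(f"unknown rule {rule!r}")
    index = sims if isinstance(sims, SimilarityIndex) else SimilarityIndex(sims)
    g = nx.Graph()
    for dec in decomps:
        for ref in _refs(dec):
            g.add_node(ref, condition=ref[0])
    for i, da in enumerate(decomps):
        for db in decomps[i + 1 :]:
            for ra in _refs(da):
                for rb in _refs(db):
                    rec = index.get(ra, rb)
                    if rule == "all_of_three":
                        hit = _qualifies(rec, k)
                    else:
                        if k >= 100.0:
                            hit = any(
                                c == 1.0
                                for name, c in zip(("node", "edge", "function"), rec.components())
                                if name not in rec.undefined
                            )
                        else:
                            hit = any(
                                c > k / 100.0
                                for name, c in zip(("node", "edge", "function"), rec.components())
                                if name not in rec.undefined
                            )
                    if hit:
                        g.add_edge(ra, rb)
    return g


def find_wam(
    decomps: Sequence[ModularDecomposition],
    sims: Iterable[SimilarityRecord] | SimilarityIndex,
    ladder: ThresholdLadder = ThresholdLadder(),
) -> list[AMRecord]:
    """Watershed module(s): the spanning overlap tuple at the highest level.

    Scans the ladder's non-terminal levels from the top down; at each level
    the all-of-three overlap graph is built, and any connected component
    containing modules from *all* input conditions is a watershed candidate.
    The first level with such a component wins; ties at that level are all
    returned, ordered by mean node similarity (descending).  Returns an
    empty list when no level qualifies.
    """
    if len(decomps) < 2:
        raise ValueError("watershed search needs at least two conditions")
    index = sims if isinstance(sims, SimilarityIndex) else SimilarityIndex(sims)
    conditions = {dec.network_ref for dec in decomps}
    for level in sorted(ladder.non_terminal(), reverse=True):
        g = overlap_graph(decomps, index, level, rule="all_of_three")
        spanning: list[AMRecord] = []
        for comp in nx.connected_components(g):
            if {ref[0] for ref in comp} == conditions:
                members = tuple(sorted(comp))
                evidence = tuple(
                    index.get(a, b)
                    for i, a in enumerate(members)
                    for b in members[i + 1 :]
                    if a[0] != b[0]
                )
                spanning.append(AMRecord("WAM", members, level=level, evidence=evidence))
        if spanning:
            spanning.sort(
                key=lambda r: -float(np.mean([e.s_n for e in r.evidence])) if r.evidence else 0.0
            )
            return spanning
    return []


def gradient_counts(
    decomps: Sequence[ModularDecomposition],
    sims: Iterable[SimilarityRecord] | SimilarityIndex,
    ladder: ThresholdLadder = ThresholdLadder(),
) -> GradientCounts:
    """Overlapping / non-overlapping module counts per condition and level.

    A module is *overlapping* at level k when any cross-condition
    counterpart qualifies under the all-of-three rule at k; the two counts
    always sum to the condition's module total.
    """
    index = sims if isinstance(sims, SimilarityIndex) else SimilarityIndex(sims)
    totals = {dec.network_ref: len(dec.modules) for dec in decomps}
    counts: dict[float, dict[str, tuple[int, int]]] = {}
    for level in ladder.levels:
        g = overlap_graph(decomps, index, level, rule="all_of_three")
        per_cond: dict[str, tuple[int, int]] = {}
        for dec in decomps:
            overlapping = sum(1 for ref in _refs(dec) if g.degree(ref) > 0)
            per_cond[dec.network_ref] = (overlapping, totals[dec.network_ref] - overlapping)
        counts[level] = per_cond
    return GradientCounts(counts=counts, module_totals=totals)


def nonoverlap_regression(
    counts: GradientCounts, condition: str
) -> tuple[float, float, float]:
    """OLS slope of non-overlapping-module count on similarity level (percent).

    Returns (slope, standard error, two-sided p from the t-test on the
    slope).  Needs at least three ladder levels.
    """
    levels = sorted(counts.counts)
    if len(levels) < 3:
        raise ValueError("regression needs at least 3 ladder levels")
    x = np.array(levels, dtype=float)
    y = np.array([counts.counts[lv][condition][1] for lv in levels], dtype=float)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.stderr), float(fit.pvalue)


def pearson_correlation(pairs: Sequence[tuple[float, float]]) -> dict:
    """Pearson r with two-sided p for paired observations.

    Zero variance in either coordinate makes the correlation undefined
    (``defined=False``, r = NaN).
    """
    if len(pairs) < 3:
        raise ValueError("correlation needs at least 3 observations")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": len(pairs), "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(pairs), "defined": True}


def function_topology_correlation(
    modules: Iterable[Module],
    functions: Mapping[str, frozenset[str]],
) -> dict:
    """Correlate node centrality within modules with module function counts.

    For every node of every module with edges, pairs the node's connecting
    percentage (intra-module degree share) with the number of significant
    terms of its module, and returns the Pearson correlation record.
    """
    pairs: list[tuple[float, float]] = []
    for m in modules:
        if not m.edges:
            continue
        n_terms = len(functions.get(m.id, frozenset()))
        for _, share in sorted(connecting_percentage(m).items()):
            pairs.append((share, float(n_terms)))
    return pearson_correlation(pairs)


def am_records_to_tsv(records: Iterable[AMRecord], path: str | Path) -> None:
    """AM calls as TSV: type, level, members, and similarity evidence."""
    with Path(path).open("w") as fh:
        fh.write("am_type\tlevel\tmembers\ts_n\ts_e\ts_f\n")
        for r in records:
            members = ";".join(f"{c}:{i}" for c, i in r.members)
            if r.evidence:
                s_n = "|".join(f"{e.s_n:.6g}" for e in r.evidence)
                s_e = "|".join(f"{e.s_e:.6g}" for e in r.evidence)
                s_f = "|".join(f"{e.s_f:.6g}" for e in r.evidence)
            else:
                s_n = s_e = s_f = ""
            level = "" if r.level is None else f"{r.level:g}"
            fh.write(f"{r.am_type}\t{level}\t{members}\t{s_n}\t{s_e}\t{s_f}\n")
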