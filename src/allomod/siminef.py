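"""SimiNEF: joint node/edge/function similarity between modules.

SimiNEF compares two modules from different conditions by three Jaccard
coefficients — over node sets (S_n), canonical undirected edge sets (S_e),
and significant function-term sets (S_f).  The combined similarity S_nef
exceeds a threshold k only when all three components exceed k
simultaneously; at the terminal "=100%" level all three must equal 1.
Each coefficient ranges from 0 (nothing in common) to 1 (identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .modules import Module, ModularDecomposition

__all__ = [
    "ModuleRef",
    "SimilarityRecord",
    "ThresholdLadder",
    "jaccard",
    "node_similarity",
    "edge_similarity",
    "function_similarity",
    "snef_exceeds",
    "pairwise_similarity",
    "connecting_percentage",
]

ModuleRef = tuple[str, str]  # (condition label, module id)


@dataclass(frozen=True)
class SimilarityRecord:
    """The (S_n, S_e, S_f) triple for one cross-condition module pair.

    ``undefined`` lists components whose Jaccard had an empty union (both
    inputs empty); such components are reported as 0.0 and can never
    qualify at any threshold.
    """

    module_a: ModuleRef
    module_b: ModuleRef
    s_n: float
    s_e: float
    s_f: float
    undefined: frozenset[str] = frozenset()

    def components(self) -> tuple[float, float, float]:
        return (self.s_n, self.s_e, self.s_f)


@dataclass(frozen=True)
class ThresholdLadder:
    """Ordered similarity levels in percent; the last level is terminal.

    The default ladder (>1%, >25%, >50%, >70%, >75%, =100%) spans the
    overlap gradient from barely-touching to identical modules.
    """

    levels: tuple[float, ...] = (1.0, 25.0, 50.0, 70.0, 75.0, 100.0)

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        if not lv:
            raise ValueError("ladder must have at least one level")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("ladder levels must be strictly increasing")
        if lv[0] <= 0 or lv[-1] > 100:
            raise ValueError("ladder levels must lie in (0, 100]")
        object.__setattr__(self, "levels", lv)

    @property
    def terminal(self) -> float:
        return self.levels[-1]

    def non_terminal(self) -> tuple[float, ...]:
        return tuple(l for l in self.levels if l < 100.0)


def jaccard(a: frozenset, b: frozenset) -> tuple[float, bool]:
    """(|a ∩ b| / |a ∪ b|, defined?); (0.0, False) when both sets are empty.

    Computed as a ratio of integers, so identical non-empty sets give
    exactly 1.0 and disjoint sets exactly 0.0.
    """
    union = a | b
    if not union:
        return 0.0, False
    return len(a & b) / len(union), True


def node_similarity(a: Module, b: Module) -> float:
    """S_n: Jaccard of the two modules' node sets."""
    value, defined = jaccard(a.nodes, b.nodes)
    if not defined:
        raise ValueError("node similarity undefined: both modules empty")
    return value


def edge_similarity(a: Module, b: Module) -> float:
    """S_e: Jaccard of canonical unordered edge sets (0.0-with-flag if both edgeless)."""
    value, _ = jaccard(a.edges, b.edges)
    return value


def function_similarity(fa: Iterable[str], fb: Iterable[str]) -> float:
    """S_f: Jaccard of significant-term sets; both-empty gives 0.0 by policy."""
    value, _ = jaccard(frozenset(fa), frozenset(fb))
    return value


def snef_exceeds(rec: SimilarityRecord, k: float, terminal: bool = False) -> bool:
    """All-three rule: S_nef > k iff S_n, S_e and S_f each exceed k (percent).

    At a terminal level (``terminal=True``, or k == 100) the predicate is
    instead exact equality of all three components to 1.  Undefined
    components always fail.
    """
    if terminal or k >= 100.0:
        if rec.undefined:
            return False
        return all(c == 1.0 for c in rec.components())
    if not 0.0 <= k < 100.0:
        raise ValueError("threshold k must lie in [0, 100)")
    frac = k / 100.0
    for name, c in zip(("node", "edge", "function"), rec.components()):
        if name in rec.undefined:
            return False
        if not c > frac:
            return False
    return True


def _similarity(a: Module, fa: frozenset[str], b: Module, fb: frozenset[str]) -> SimilarityRecord:
    undefined: set[str] = set()
    s_n, def_n = jaccard(a.nodes, b.nodes)
    if not def_n:
        undefined.add("node")
    s_e, def_e = jaccard(a.edges, b.edges)
    if not def_e:
        undefined.add("edge")
    s_f, def_f = jaccard(fa, fb)
    if not def_f:
        undefined.add("function")
    return SimilarityRecord(
        module_a=(a.condition, a.id),
        module_b=(b.condition, b.id),
        s_n=s_n,
        s_e=s_e,
        s_f=s_f,
        undefined=frozenset(undefined),
    )


def pairwise_similarity(
    dec_a: ModularDecomposition,
    dec_b: ModularDecomposition,
    functions: Mapping[ModuleRef, frozenset[str]] | None = None,
) -> list[SimilarityRecord]:
    """All |A| x |B| similarity records between two conditions' modules.

    ``functions`` maps (condition, module id) to the module's significant
    term set F(m); missing entries are treated as empty (uncharacterized).
    Comparing a decomposition against itself (same condition label) is
    refused: the taxonomy only compares across conditions.
    """
    if dec_a.network_ref == dec_b.network_ref:
        raise ValueError("pairwise similarity is defined across different conditions")
    functions = functions or {}
    out: list[SimilarityRecord] = []
    for ma in dec_a.modules:
        fa = frozenset(functions.get((ma.condition, ma.id), frozenset()))
        for mb in dec_b.modules:
            fb = frozenset(functions.get((mb.condition, mb.id), frozenset()))
            out.append(_similarity(ma, fa, mb, fb))
    return out


def connecting_percentage(m: Module) -> dict[str, float]:
    """Each node's intra-module degree share: deg(v) / total module degree.

    Measures how much of the module's wiring runs through a node; the
    shares sum to 1 over the module.
    """
    if not m.edges:
        raise ValueError(f"module {m.id} has no edges; connecting percentage undefined")
    deg: dict[str, int] = {v: 0 for v in m.nodes}
    for u, v in m.edges:
        deg[u] += 1
        deg[v] += 1
    total = 2 * len(m.edges)
    return {v: d / total for v, d in deg.items()}


def records_to_tsv(records: list[SimilarityRecord], path: str | Path) -> None:
    """Long-format TSV: cond_a, module_a, cond_b, module_b, s_n, s_e, s_f, flags."""
    with Path(path).open("w") as fh:
        fh.write("cond_a\tmodule_a\tcond_b\tmodule_b\ts_n\ts_e\ts_f\tundefined\n")
        for r in records:
            flags = ",".join(sorted(r.undefined))
            fh.write(
                f"{r.module_a[0]}\t{r.module_a[1]}\t{r.module_b[0]}\t{r.module_b[1]}"
                f"\t{r.s_n:.10g}\t{r.s_e:.10g}\t{r.s_f:.10g}\t{flags}\n"
            )
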