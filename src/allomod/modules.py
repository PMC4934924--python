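"""Core containers for network modules and modular decompositions."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .network import canonical_edge

__all__ = ["Module", "ModularDecomposition", "module_from_nodes"]


@dataclass(frozen=True)
class Module:
    """A candidate functional module: a node set with its induced edges.

    ``edges`` are exactly the edges induced by ``nodes`` in the parent
    network, stored in canonical (sorted-pair) form.  ``score`` is
    method-specific (e.g. the MCODE density score); ``condition`` names the
    network the module came from.
    """

    id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    score: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValueError("a module needs at least one node")
        for u, v in self.edges:
            if u > v:
                raise ValueError(f"edge ({u},{v}) not in canonical order")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references a node outside the module")

    def subgraph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def size(self) -> int:
        return len(self.nodes)


def module_from_nodes(
    net: nx.Graph, nodes: Iterable[str], id: str, score: float = 0.0, condition: str = ""
) -> Module:
    """Build a module as the vertex-induced subgraph of ``nodes`` in ``net``."""
    nodeset = frozenset(nodes)
    edges = frozenset(
        canonical_edge(u, v) for u, v in net.subgraph(nodeset).edges()
    )
    return Module(id=id, nodes=nodeset, edges=edges, score=score, condition=condition)


@dataclass
class ModularDecomposition:
    """The output of one detection method at one parameter setting.

    For partitioning methods (MCL, affinity propagation) the modules cover
    every node exactly once; MCODE modules may overlap and need not cover
    the network.
    """

    modules: list[Module]
    method: str
    params: dict = field(default_factory=dict)
    network_ref: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def node_cover(self) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.nodes
        return out

    def is_partition_of(self, nodes: Iterable[str]) -> bool:
        seen: set[str] = set()
        for m in self.modules:
            if seen & m.nodes:
                return False
            seen |= m.nodes
        return seen == set(nodes)

    def union_graph(self) -> nx.Graph:
        """Union of the module-induced subgraphs (the graph entropy is scored on)."""
        g = nx.Graph()
        for m in self.modules:
            g.add_nodes_from(m.nodes)
            g.add_edges_from(m.edges)
        return g

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Serialize as (module_id, node) rows plus a JSON metadata sidecar."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("module_id\tnode\n")
            for m in self.modules:
                for n in sorted(m.nodes):
                    fh.write(f"{m.id}\t{n}\n")
        meta = {
            "method": self.method,
            "params": self.params,
            "network_ref": self.network_ref,
            "warnings": self.warnings,
            "scores": {m.id: m.score for m in self.modules},
        }
        with path.with_suffix(path.suffix + ".json").open("w") as fh:
            json.dump(meta, fh, indent=2, default=str)

    @classmethod
    def from_tsv(cls, path: str | Path, net: nx.Graph | None = None) -> "ModularDecomposition":
        """Read a (module_id, node) TSV plus its JSON metadata sidecar.

        If ``net`` is given, module edges are re-induced from it; otherwise
        modules carry empty edge sets.
        """
        path = Path(path)
        members: dict[str, list[str]] = {}
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("module_id"):
                raise ValueError(f"{path}: expected a 'module_id\\tnode' header")
            for line in fh:
                if not line.strip():
                    continue
                mid, node = line.rstrip("\n").split("\t")[:2]
                members.setdefault(mid, []).append(node)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        scores = meta.get("scores", {})
        condition = meta.get("network_ref", "")
        modules = []
        for mid, nodes in members.items():
            if net is not None:
                modules.append(
                    module_from_nodes(net, nodes, id=mid, score=float(scores.get(mid, 0.0)), condition=condition)
                )
            else:
                modules.append(
                    Module(mid, frozenset(nodes), frozenset(), float(scores.get(mid, 0.0)), condition)
                )
        return cls(
            modules=modules,
            method=meta.get("method", "unknown"),
            params=meta.get("params", {}),
            network_ref=condition,
            warnings=list(meta.get("warnings", [])),
        )

    def to_gmt(self, path: str | Path) -> None:
        """GMT-style output: one module per line (id, description, members)."""
        with Path(path).open("w") as fh:
            for m in self.modules:
                members = "\t".join(sorted(m.nodes))
                fh.write(f"{m.id}\t{self.method}:{self.network_ref}\t{members}\n")
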