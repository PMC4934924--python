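"""Interaction-network I/O and condition-specific target-network construction.

Networks are undirected simple graphs (:class:`networkx.Graph`) over opaque
string node identifiers (Entrez gene IDs in the motivating use case).  A
*target network* is the subgraph of a global interaction network induced by
the differentially expressed genes of one condition.

Expression data live in a :class:`pandas.DataFrame` with genes as the index
and condition labels as columns; values are unitless log-ratio-like scores.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "canonical_edge",
    "read_edge_list",
    "write_edge_list",
    "merge_networks",
    "read_expression",
    "mean_center",
    "select_differential",
    "induce_target_network",
    "topological_summary",
]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list rows; carries the 1-based line number."""


class EmptyNetworkError(ValueError):
    """Raised when a parsed file yields no nodes at all."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered form of an edge: the lexicographically sorted pair."""
    return (u, v) if u <= v else (v, u)


def _simple_graph(pairs: Iterable[tuple[str, str]], name: str = "") -> nx.Graph:
    """Build a simple graph, dropping self-loops and duplicate edges.

    Returns the graph and logs how many records were dropped.
    """
    g = nx.Graph(name=name)
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for u, v in pairs:
        if u == v:
            dropped += 1
            continue
        e = canonical_edge(u, v)
        if e in seen:
            dropped += 1
            continue
        seen.add(e)
        g.add_edge(*e)
    if dropped:
        logger.info("dropped %d duplicate/self-loop records", dropped)
    g.graph["n_dropped_records"] = dropped
    return g


def read_edge_list(path: str | Path, format: str = "tsv", name: str | None = None) -> nx.Graph:
    """Read an undirected interaction network from a TSV or SIF edge list.

    TSV rows are ``nodeA <tab> nodeB [extra columns ignored]``; SIF rows are
    ``nodeA <tab> relation <tab> nodeB``.  Duplicate edges (in either
    orientation) and self-interactions are removed; the count of dropped
    records is logged and stored as ``graph["n_dropped_records"]``.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "tsv":
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: expected >=2 tab-separated columns, got {line!r}"
                    )
                pairs.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: SIF rows need 'nodeA<TAB>relation<TAB>nodeB...', got {line!r}"
                    )
                # one source node, arbitrary number of targets
                src = fields[0]
                for tgt in fields[2:]:
                    pairs.append((src, tgt))
    g = _simple_graph(pairs, name=name or path.stem)
    if g.number_of_nodes() == 0:
        raise EmptyNetworkError(f"{path}: no valid interactions found")
    return g


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a two-column TSV of canonical edges, sorted."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(canonical_edge(u, v) for u, v in net.edges()):
            fh.write(f"{u}\t{v}\n")


def merge_networks(networks: list[nx.Graph], name: str = "merged") -> nx.Graph:
    """Node/edge union of several interaction networks (simple graph preserved).

    Mirrors the integration of several interaction databases into one global
    network: duplicated interactions collapse, self-interactions never enter.
    """
    if not networks:
        raise ValueError("need at least one network to merge")
    g = nx.Graph(name=name)
    for net in networks:
        g.add_nodes_from(net.nodes())
        g.add_edges_from(canonical_edge(u, v) for u, v in net.edges() if u != v)
    return g


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (first column gene IDs, header of condition labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in expression table: {dups[:5]}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression table contains non-finite values")
    return df


def mean_center(expr: pd.DataFrame, axis: str = "gene") -> pd.DataFrame:
    """Mean-centered normalisation: subtract each gene's (or condition's) mean.

    Idempotent: centering an already-centered table is the identity (up to
    floating-point round-off).
    """
    if expr.size == 0:
        raise ValueError("cannot mean-center an empty expression table")
    if axis == "gene":
        return expr.sub(expr.mean(axis=1), axis=0)
    if axis == "condition":
        return expr.sub(expr.mean(axis=0), axis=1)
    raise ValueError(f"axis must be 'gene' or 'condition', got {axis!r}")


def select_differential(
    expr: pd.DataFrame,
    condition: str,
    threshold: float = 1.0,
    mode: str = "signed",
) -> set[str]:
    """Differentially expressed genes of one condition.

    ``signed`` keeps genes with expression value strictly greater than the
    threshold (the literal "greater than one" rule); ``absolute`` applies the
    threshold to the magnitude, which is the natural reading for
    mean-centered (signed) data.  The inequality is strict in both modes.
    """
    if condition not in expr.columns:
        raise KeyError(f"unknown condition label: {condition!r}")
    col = expr[condition]
    if mode == "signed":
        mask = col > threshold
    elif mode == "absolute":
        mask = col.abs() > threshold
    else:
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    return set(expr.index[mask].astype(str))


def induce_target_network(global_net: nx.Graph, genes: set[str], label: str) -> nx.Graph:
    """Subgraph of the global network induced by a differential gene set.

    Genes absent from the global network are silently dropped (count logged).
    The result carries ``graph["name"] = label`` and
    ``graph["source_genes"]`` = the inducing gene set.
    """
    present = set(genes) & set(global_net.nodes())
    missing = len(genes) - len(present)
    if missing:
        logger.info("%s: %d differential genes absent from the global network", label, missing)
    sub = nx.Graph(global_net.subgraph(present))
    sub.graph.clear()
    sub.graph["name"] = label
    sub.graph["source_genes"] = set(genes)
    sub.graph["n_missing_genes"] = missing
    return sub


def topological_summary(net: nx.Graph) -> dict:
    """Node/edge counts, degree histogram, and a log-log power-law fit.

    The slope is a least-squares fit of log(frequency) on log(degree) over
    degrees with nonzero frequency (degree-0 nodes are excluded from the
    fit).  Scale-free-like networks give a negative slope.  With fewer than
    two distinct positive degrees the slope is undefined
    (``slope_defined=False``).
    """
    if net.number_of_nodes() < 2:
        raise ValueError("topological summary needs at least two nodes")
    degrees = [d for _, d in net.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    pos = sorted((d, c) for d, c in hist.items() if d > 0)
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "degree_histogram": dict(sorted(hist.items())),
        "slope_defined": False,
        "slope": math.nan,
        "r_squared": math.nan,
    }
    if len(pos) >= 2:
        x = np.log([d for d, _ in pos])
        y = np.log([c for _, c in pos])
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        summary["slope_defined"] = True
        summary["slope"] = float(slope)
        summary["r_squared"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return summary


def summary_to_json(summary: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(summary, fh, indent=2, default=str)
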