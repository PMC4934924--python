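"""Network-structure entropy and the minimum-entropy selection criterion.

The structure entropy of a graph is the Shannon entropy (in nats) of the
degree-based node-importance distribution

    I_i = k_i / sum_j k_j,        E = -sum_i I_i ln I_i.

Over connected graphs on N nodes it is maximised (ln N) by regular graphs
and minimised by the star, whose entropy has the closed form

    E_min(N) = ln(4(N - 1)) / 2.

Star-like, hub-dominated ("ordered") topologies therefore score low.  The
minimum-entropy criterion picks, among candidate modular decompositions of
a network, the one whose module-induced graph has the lowest structure
entropy; significance is assessed against decompositions of
degree-preserving rewirings of the network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .detect import _ESTIMATORS, filter_modules
from .modules import ModularDecomposition

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyReport",
    "RandomizationResult",
    "node_importance",
    "structure_entropy",
    "min_entropy",
    "decomposition_entropy",
    "empirical_p",
    "select_min_entropy",
    "degree_preserving_randomize",
    "entropy_significance",
]


@dataclass
class EntropyReport:
    E: float
    E_min: float
    N: int
    importances: dict[str, float] = field(default_factory=dict)


@dataclass
class RandomizationResult:
    observed_E: float
    ensemble_E: list[float]
    n_random: int
    p_value: float
    seed: int
    ensemble_mean: float
    n_skipped: int = 0
    p_ttest: float | None = None


def node_importance(net: nx.Graph) -> dict[str, float]:
    """Degree share of each node: I_i = k_i / sum_j k_j (sums to 1)."""
    total = 2 * net.number_of_edges()
    if total == 0:
        raise ValueError("node importance is undefined for an edgeless graph")
    return {v: d / total for v, d in net.degree()}


def structure_entropy(net: nx.Graph) -> float:
    """E = -sum I_i ln I_i in nats; degree-0 nodes contribute nothing."""
    imp = node_importance(net)
    return float(-sum(p * math.log(p) for p in imp.values() if p > 0))


def min_entropy(n_nodes: int) -> float:
    """Star-graph lower bound E_min(N) = ln(4(N-1)) / 2 for N >= 2."""
    if n_nodes < 2:
        raise ValueError("minimum entropy requires at least 2 nodes")
    return 0.5 * math.log(4.0 * (n_nodes - 1))


def decomposition_entropy(
    dec: ModularDecomposition,
    degrees: str = "union",
    parent: nx.Graph | None = None,
) -> EntropyReport:
    """Structure entropy of a modular decomposition.

    Scored on the union of the module-induced subgraphs — the only graph
    that varies with the clustering — with degrees counted inside that union
    (``degrees="union"``, the default).  When the modules cover the whole
    network this reduces to the plain network entropy.  ``degrees="global"``
    instead keeps each node's degree in the ``parent`` network and is
    provided for sensitivity analysis.
    """
    g = dec.union_graph()
    if g.number_of_edges() == 0:
        raise ValueError("all modules are edgeless; entropy undefined")
    if degrees == "union":
        imp = node_importance(g)
    elif degrees == "global":
        if parent is None:
            raise ValueError("degrees='global' requires the parent network")
        total = sum(parent.degree(v) for v in g.nodes())
        if total == 0:
            raise ValueError("all module nodes are isolated in the parent network")
        imp = {v: parent.degree(v) / total for v in g.nodes()}
    else:
        raise ValueError("degrees must be 'union' or 'global'")
    e = float(-sum(p * math.log(p) for p in imp.values() if p > 0))
    return EntropyReport(E=e, E_min=min_entropy(g.number_of_nodes()), N=g.number_of_nodes(), importances=imp)


def select_min_entropy(
    decs: list[ModularDecomposition],
) -> tuple[ModularDecomposition, pd.DataFrame]:
    """Pick the decomposition with the smallest structure entropy.

    Ties break toward fewer modules, then by method name.  Returns the
    winner plus a per-candidate report table (method, params, module count,
    mean module size, E, E_min); candidates whose entropy is undefined are
    kept in the table with NaN entropy but never selected.
    """
    rows = []
    keyed: list[tuple[tuple, int]] = []
    for i, dec in enumerate(decs):
        try:
            rep = decomposition_entropy(dec)
            e, e_min = rep.E, rep.E_min
        except ValueError:
            e, e_min = math.nan, math.nan
        sizes = [m.size for m in dec.modules]
        rows.append(
            {
                "method": dec.method,
                "params": repr(dec.params),
                "n_modules": len(dec.modules),
                "mean_size": float(np.mean(sizes)) if sizes else 0.0,
                "E": e,
                "E_min": e_min,
            }
        )
        if not math.isnan(e):
            keyed.append(((e, len(dec.modules), dec.method), i))
    table = pd.DataFrame(rows)
    if not keyed:
        raise ValueError("no candidate decomposition has a computable entropy")
    best_idx = min(keyed)[1]
    return decs[best_idx], table


def empirical_p(observed: float, ensemble: list[float]) -> float:
    """One-sided empirical rank p-value with add-one smoothing.

    p = (1 + #{replicates with E <= observed}) / (n + 1), so an observed
    value below every one of n replicates gives p = 1/(n+1) (1/51 for the
    standard 50-network ensemble) and one above them all gives 1.0.  Always
    in (0, 1].
    """
    if not ensemble:
        raise ValueError("empirical p-value needs a non-empty ensemble")
    return (1 + sum(e <= observed for e in ensemble)) / (len(ensemble) + 1)


def degree_preserving_randomize(
    net: nx.Graph, n_swap_multiplier: int = 10, seed: int = 0
) -> nx.Graph:
    """Rewire a graph by double-edge swaps, preserving every node's degree.

    Each attempt picks two distinct edges (a,b),(c,d) and proposes
    (a,d),(c,b); proposals creating self-loops or parallel edges are
    rejected, so the result stays a simple graph with the exact degree
    multiset of the input.  ``n_swap_multiplier`` x |edges| attempts are
    made.  Graphs admitting no valid swap (e.g. a triangle) come back as an
    identical copy with a warning.
    """
    if net.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.nodes())
    g.add_edges_from(net.edges())
    g.graph.update(net.graph)
    edges = list(g.edges())
    n_attempts = n_swap_multiplier * len(edges)
    n_success = 0
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        n_success += 1
    if n_success == 0:
        logger.warning("no valid double-edge swap found; returning an identical copy")
        g.graph["rewiring_warning"] = "no valid swap on this degree sequence"
    g.graph["n_swaps_applied"] = n_success
    return g


def entropy_significance(
    net: nx.Graph,
    method: str,
    params: dict | None = None,
    n_random: int = 50,
    seed: int = 0,
    min_nodes: int = 3,
    n_swap_multiplier: int = 10,
) -> RandomizationResult:
    """Empirical significance of a decomposition's entropy vs a rewired null.

    Runs the given detection method (with ``params``) on the original
    network and on ``n_random`` degree-preserving rewirings, scoring each
    decomposition (modules with >= ``min_nodes`` nodes) by structure
    entropy.  The one-sided empirical p-value with add-one smoothing is

        p = (1 + #{replicates with E <= observed}) / (n_used + 1),

    so an observed entropy below every replicate gives p = 1/(n+1).
    Replicates where detection fails or yields no scorable modules are
    skipped and counted.  A one-sample t-test p-value on the ensemble is
    reported alongside.
    """
    params = dict(params or {})
    cls = _ESTIMATORS[method]

    def _entropy_of(g: nx.Graph) -> float:
        dec = filter_modules(cls(**params).fit_predict(g), min_nodes=min_nodes)
        return decomposition_entropy(dec).E

    observed = _entropy_of(net)
    rng = np.random.default_rng(seed)
    ensemble: list[float] = []
    n_skipped = 0
    for _ in range(n_random):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            rand = degree_preserving_randomize(net, n_swap_multiplier, seed=rep_seed)
            ensemble.append(_entropy_of(rand))
        except ValueError as exc:
            n_skipped += 1
            logger.info("replicate skipped: %s", exc)
    if not ensemble:
        raise ValueError("every null replicate failed; cannot compute significance")
    n_used = len(ensemble)
    p = empirical_p(observed, ensemble)
    if len(ensemble) > 1 and float(np.std(ensemble)) > 0:
        p_t = float(stats.ttest_1samp(ensemble, observed).pvalue)
    else:
        p_t = None
    return RandomizationResult(
        observed_E=observed,
        ensemble_E=ensemble,
        n_random=n_used,
        p_value=float(p),
        seed=seed,
        ensemble_mean=float(np.mean(ensemble)),
        n_skipped=n_skipped,
        p_ttest=p_t,
    )
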