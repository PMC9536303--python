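"""Per-neoplasm miRNA similarity networks: construction, pruning, topology.

Each neoplasm group gets one weighted undirected graph whose nodes are the
miRNAs associated with that group and whose edges are the globally computed
similarity edges restricted to those nodes.  Networks are then pruned to the
links whose combined weight lies strictly above the nearest-rank 90th
percentile of that network's weights, after which isolated nodes are removed.

The nearest-rank convention (cutoff = value at rank ceil(p/100 * E) of the
ascending weights, keep strictly greater) makes the retained count exactly
E - ceil(p/100 * E) when all E weights are distinct — e.g. 2,415 distinct
weights at the 90th percentile leave 241 edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .harmonize import AssociationRecord
from .mirna_similarity import SimilarityEdge

logger = logging.getLogger(__name__)

DEFAULT_PRUNE_PERCENTILE = 90.0


@dataclass
class NeoplasmNetwork:
    """Weighted undirected miRNA graph for one neoplasm group."""

    group: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    pruned: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_clique(self, members: frozenset[str] | set[str]) -> bool:
        """True when every pair of ``members`` is an edge of this network."""
        ms = sorted(members)
        g = self.graph
        return all(
            g.has_edge(a, b) for i, a in enumerate(ms) for b in ms[i + 1:]
        )


@dataclass
class TopologyReport:
    group: str
    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    avg_clustering: float
    dispersion_index: float
    poisson_gof_p: float

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "avg_clustering": self.avg_clustering,
            "dispersion_index": self.dispersion_index,
            "poisson_gof_p": self.poisson_gof_p,
        }


def build_neoplasm_network(
    group: str,
    associations: list[AssociationRecord],
    edges: list[SimilarityEdge],
    known_groups: set[str] | None = None,
) -> NeoplasmNetwork:
    """Restrict the global similarity edge set to one group's miRNAs.

    Nodes are all miRNAs associated with the group (including ones without
    any surviving similarity edge); the pruning step removes isolates later.
    A group outside the configured universe (``known_groups``, defaulting to
    the groups present in the records) is an error; a known group with no
    associations yields an empty network.
    """
    universe = known_groups if known_groups is not None else {r.group for r in associations}
    if group not in universe:
        raise KeyError(f"group {group!r} absent from the group universe")
    nodes = {r.mirna for r in associations if r.group == group}
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for e in edges:
        if e.mirna_a in nodes and e.mirna_b in nodes:
            g.add_edge(
                e.mirna_a, e.mirna_b,
                w_sym=e.w_sym, w_asym=e.w_asym, w_combined=e.w_combined,
            )
    return NeoplasmNetwork(group=group, graph=g, pruned=False)


def nearest_rank_cutoff(weights: list[float], percentile: float) -> float:
    """Value at ascending rank ceil(percentile/100 * N); no interpolation."""
    if not weights:
        raise ValueError("no weights to take a percentile of")
    ordered = sorted(weights)
    rank = math.ceil(percentile / 100.0 * len(ordered))
    return ordered[max(rank, 1) - 1]


def prune_top_decile(
    net: NeoplasmNetwork,
    percentile: float = DEFAULT_PRUNE_PERCENTILE,
    weight_attr: str = "w_combined",
) -> NeoplasmNetwork:
    """Keep edges strictly above the nearest-rank percentile cutoff.

    Ties at the cutoff weight are all dropped (strictness applies to the
    value, not the rank), so the result is order-independent.  Nodes left
    isolated are removed.  Pruning an already-pruned network is an error.
    """
    if net.pruned:
        raise ValueError(f"network {net.group!r} is already pruned")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    g = nx.Graph()
    if net.n_edges > 0:
        weights = [d[weight_attr] for _, _, d in net.graph.edges(data=True)]
        cutoff = nearest_rank_cutoff(weights, percentile)
        for a, b, d in net.graph.edges(data=True):
            if d[weight_attr] > cutoff:
                g.add_edge(a, b, **d)
    return NeoplasmNetwork(group=net.group, graph=g, pruned=True)


def clustering_coefficients(net: NeoplasmNetwork) -> tuple[dict[str, float], float]:
    """Local clustering coefficient per node and the graph average.

    Local value is the fraction of a node's neighbour pairs that are
    connected; nodes of degree < 2 score 0.  An empty network reports an
    average of 0 with a warning.
    """
    if net.graph.number_of_nodes() == 0:
        logger.warning("clustering of empty network %r reported as 0", net.group)
        return {}, 0.0
    local = nx.clustering(net.graph)
    return dict(local), float(np.mean(list(local.values())))


def degree_distribution_fit(net: NeoplasmNetwork) -> TopologyReport:
    """Degree histogram, dispersion index, and Poisson goodness of fit.

    The chi-square test compares observed degree counts with Poisson(mean
    degree) expectations, merging adjacent bins from both tails until every
    expected count is at least 5; one degree of freedom is charged for the
    estimated mean.  Graphs too small to leave a positive degree of freedom
    report p = 1 (the fit is unfalsifiable at that size).
    """
    degrees = np.array([d for _, d in net.graph.degree()], dtype=float)
    if degrees.size < 2:
        raise ValueError("degree-distribution fit needs at least 2 nodes")
    mean = degrees.mean()
    var = degrees.var(ddof=1)
    dispersion = var / mean if mean > 0 else 0.0

    hist: dict[int, int] = {}
    for d in degrees.astype(int):
        hist[int(d)] = hist.get(int(d), 0) + 1

    p_value = _poisson_gof_p(degrees, mean)
    _, avg_cc = clustering_coefficients(net)
    return TopologyReport(
        group=net.group,
        n_nodes=int(degrees.size),
        n_edges=net.graph.number_of_edges(),
        degree_histogram=hist,
        avg_clustering=avg_cc,
        dispersion_index=float(dispersion),
        poisson_gof_p=p_value,
    )


def _poisson_gof_p(degrees: np.ndarray, lam: float) -> float:
    """Chi-square GOF p-value of degrees against Poisson(lam), tail-binned."""
    n = degrees.size
    if lam <= 0:
        return 1.0
    kmax = int(degrees.max())
    ks = np.arange(0, kmax + 1)
    expected = stats.poisson.pmf(ks, lam) * n
    observed = np.array([(degrees == k).sum() for k in ks], dtype=float)
    # open upper tail absorbs P(X > kmax)
    expected = np.append(expected, n * stats.poisson.sf(kmax, lam))
    observed = np.append(observed, 0.0)
    obs_b, exp_b = _merge_bins(observed, expected, min_expected=5.0)
    dof = len(obs_b) - 1 - 1  # one parameter (lam) estimated
    if dof < 1:
        return 1.0
    chi2 = float(((obs_b - exp_b) ** 2 / exp_b).sum())
    return float(stats.chi2.sf(chi2, dof))


def _merge_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent bins inward from both ends until expected >= threshold."""
    obs = list(observed)
    exp = list(expected)

    def merge(src: int, dst: int) -> None:
        exp[dst] += exp[src]
        obs[dst] += obs[src]
        del exp[src], obs[src]

    # collapse from the right, then the left
    while len(exp) > 1 and exp[-1] < min_expected:
        merge(len(exp) - 1, len(exp) - 2)
    while len(exp) > 1 and exp[0] < min_expected:
        merge(0, 1)
    # interior sweep for any remaining small bins
    i = 0
    while i < len(exp):
        if exp[i] < min_expected and len(exp) > 1:
            merge(i, i + 1 if i + 1 < len(exp) else i - 1)
            i = 0
        else:
            i += 1
    return np.array(obs), np.array(exp)


def write_edge_list(net: NeoplasmNetwork, path) -> None:
    """Export the network as a weighted edge-list TSV."""
    import pandas as pd

    rows = [
        {
            "mirna_a": a, "mirna_b": b,
            "w_sym": d.get("w_sym"), "w_asym": d.get("w_asym"),
            "w_combined": d.get("w_combined"),
        }
        for a, b, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["mirna_a", "mirna_b", "w_sym", "w_asym", "w_combined"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: NeoplasmNetwork, path) -> None:
    """Export the network as GraphML (None weights dropped per edge)."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for a, b, d in net.graph.edges(data=True):
        g.add_edge(a, b, **{k: v for k, v in d.items() if v is not None})
    nx.write_graphml(g, path)
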