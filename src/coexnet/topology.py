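"""Graph-topology statistics for co-expression networks.

All statistics operate on the unweighted skeleton of the network.  Note the
domain convention used throughout: the network "diameter" is the *average*
shortest-path length over all node pairs, restricted to pairs within the same
connected component so it stays finite on fragmented graphs.  The classical
longest-shortest-path quantity is exposed separately as
:func:`max_eccentricity` to avoid confusion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean node degree, ``2 E / N``."""
    if n_nodes <= 0:
        raise ValueError("average degree undefined for an empty node set")
    return 2.0 * n_edges / n_nodes


def _pairwise_distances(g: nx.Graph) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(g, format="csr", weight=None)
    return shortest_path(adj, method="D", directed=False, unweighted=True)


def network_diameter(g: nx.Graph) -> float:
    """Average shortest-path length over intra-component node pairs (unweighted hops)."""
    if g.number_of_edges() == 0:
        raise ValueError("diameter undefined: graph has no edges")
    dist = _pairwise_distances(g)
    iu = np.triu_indices(dist.shape[0], k=1)
    finite = dist[iu][np.isfinite(dist[iu])]
    if finite.size == 0:
        raise ValueError("diameter undefined: no connected node pair")
    return float(finite.mean())


def max_eccentricity(g: nx.Graph) -> int:
    """Classical diameter: the longest shortest path within any component."""
    if g.number_of_edges() == 0:
        raise ValueError("undefined: graph has no edges")
    dist = _pairwise_distances(g)
    finite = dist[np.isfinite(dist)]
    return int(finite.max())


def betweenness(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness centrality per node.

    Unnormalized by default: the value is the number of unordered node pairs
    whose shortest paths pass through the node, with ties split equally among
    equal-length paths.
    """
    return dict(nx.betweenness_centrality(g, normalized=normalized))


def clustering_coefficient(g: nx.Graph) -> tuple[dict[str, float], float]:
    """Local clustering coefficient per node plus the network mean.

    For a node of degree ``k >= 2`` the coefficient is
    ``2 * links_among_neighbors / (k (k - 1))``; nodes of degree < 2 score 0.
    """
    local = {n: float(c) for n, c in nx.clustering(g).items()}
    mean = float(np.mean(list(local.values()))) if local else 0.0
    return local, mean


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """Exact histogram of node degrees (degree -> count)."""
    return dict(Counter(d for _, d in g.degree()))


@dataclass
class PowerLawFit:
    """OLS fit of log10(count) on log10(degree) over nonzero histogram bins."""

    slope: float
    intercept: float
    r_squared: float


def power_law_fit(histogram: dict[int, int]) -> PowerLawFit:
    """Assess scale-free character by a log-log regression on the degree histogram.

    Requires at least 3 distinct degrees with nonzero counts.  The slope is
    the power-law exponent estimate (expected negative for heavy-tailed
    degree distributions); R^2 measures log-log linearity.
    """
    points = [(d, c) for d, c in histogram.items() if c > 0 and d > 0]
    if len(points) < 3:
        raise ValueError("power-law fit needs >= 3 distinct degrees with nonzero count")
    x = np.log10([d for d, _ in points])
    y = np.log10([c for _, c in points])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(slope=float(slope), intercept=float(intercept), r_squared=float(r2))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    degree_histogram: dict[int, int]
    diameter: float  # average shortest path (domain convention)
    max_eccentricity: int
    mean_clustering: float
    n_components: int
    density: float
    betweenness: dict[str, float]
    clustering: dict[str, float]
    power_law: PowerLawFit | None


def summarize(g: nx.Graph) -> TopologySummary:
    """Compute the full per-network and per-gene topology report."""
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("cannot summarize an empty graph")
    hist = degree_distribution(g)
    local, mean_c = clustering_coefficient(g)
    try:
        fit = power_law_fit(hist)
    except ValueError:
        fit = None
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        average_degree=average_degree(n, m),
        degree_histogram=hist,
        diameter=network_diameter(g) if m else 0.0,
        max_eccentricity=max_eccentricity(g) if m else 0,
        mean_clustering=mean_c,
        n_components=nx.number_connected_components(g),
        density=2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        betweenness=betweenness(g),
        clustering=local,
        power_law=fit,
    )


def node_table(summary: TopologySummary, g: nx.Graph) -> pd.DataFrame:
    """Per-gene table of degree, betweenness and clustering coefficient."""
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "gene": nodes,
            "degree": [g.degree(v) for v in nodes],
            "betweenness": [summary.betweenness[v] for v in nodes],
            "clustering": [summary.clustering[v] for v in nodes],
        }
    )
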