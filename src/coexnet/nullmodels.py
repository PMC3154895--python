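"""Random-graph null models and the edge-overlap non-randomness test.

Two nulls are provided: degree-preserving Maslov-Sneppen rewiring (repeated
double-edge swaps) and an Erdős–Rényi G(n, m) model with the original node set
and the original edge count drawn uniformly at random.  Each null is sampled R
times, the shared-edge count with the observed network is recorded, and a
z-score ``(m_observed - mean_overlap) / sd_overlap`` quantifies how far the
observed network lies from the null ensemble.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

MODELS = ("maslov_sneppen", "erdos_renyi")


def maslov_sneppen(
    g: nx.Graph,
    seed: int = 0,
    n_swaps: int | None = None,
    max_tries: int | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``n_swaps`` *successful* swaps (default ``4 * n_edges``): two
    edges (a, b) and (c, d) are replaced by (a, d) and (c, b); candidate swaps
    that would create a self-loop or a parallel edge are rejected and do not
    count.  Counting successes rather than attempts guarantees the intended
    amount of mixing regardless of the rejection rate.  If no valid swap
    exists (e.g. a triangle) the attempt budget runs out and the graph is
    returned unchanged.
    """
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    m = g.number_of_edges()
    if n_swaps is None:
        n_swaps = 4 * m
    if max_tries is None:
        max_tries = max(100 * n_swaps, 1000)
    rng = random.Random(seed)
    edges = [tuple(e) for e in g.edges]
    edge_set = {frozenset(e) for e in edges}
    swaps = tries = 0
    while swaps < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.randrange(m), rng.randrange(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # both pairings of the two edges are reachable
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if frozenset((a, d)) in edge_set or frozenset((c, b)) in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(frozenset((a, d)))
        edge_set.add(frozenset((c, b)))
        edges[i] = (a, d)
        edges[j] = (c, b)
        swaps += 1
    if swaps < n_swaps:
        logger.warning(
            "maslov_sneppen: only %d/%d swaps succeeded within %d attempts",
            swaps,
            n_swaps,
            max_tries,
        )
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(edges)
    return out


def erdos_renyi_like(g: nx.Graph, seed: int = 0) -> nx.Graph:
    """G(n, m) null: same node set, same edge count, edges uniform without replacement."""
    nodes = sorted(g.nodes)
    n, m = len(nodes), g.number_of_edges()
    total = n * (n - 1) // 2
    if m > total:
        raise ValueError(f"cannot place {m} edges among {n} nodes ({total} pairs)")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[iu[k]], nodes[ju[k]]) for k in chosen)
    return out


def edge_overlap(g1: nx.Graph, g2: nx.Graph) -> int:
    """Number of unordered node pairs that are edges in both graphs."""
    if g1.number_of_edges() > g2.number_of_edges():
        g1, g2 = g2, g1
    return sum(1 for u, v in g1.edges if g2.has_edge(u, v))


@dataclass
class NullModelSummary:
    """Overlap statistics of one null-model ensemble against the observed network."""

    model: str
    n_replicates: int
    m_observed: int
    overlaps: list[int]
    mean_overlap: float
    sd_overlap: float
    z: float | None  # None when sd_overlap is zero


def z_score(m_observed: float, mean_overlap: float, sd_overlap: float) -> float:
    """Standardized distance of the observed edge count from the null overlap."""
    if sd_overlap <= 0:
        raise ValueError("z undefined for zero overlap spread")
    return (m_observed - mean_overlap) / sd_overlap


def null_summary(
    g: nx.Graph,
    model: str,
    n_replicates: int = 200,
    seed: int = 0,
) -> NullModelSummary:
    """Sample ``n_replicates`` null graphs and summarize their edge overlap with ``g``.

    Per-replicate seeds are derived deterministically from ``seed``.  The SD is
    the sample (n-1) standard deviation; if it is zero the z-score is reported
    as undefined (``None``) with a warning.
    """
    if model not in MODELS:
        raise ValueError(f"unknown null model {model!r}; expected one of {MODELS}")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates).tolist()
    sampler = maslov_sneppen if model == "maslov_sneppen" else erdos_renyi_like
    overlaps = [edge_overlap(g, sampler(g, seed=int(s))) for s in child_seeds]
    mean = float(np.mean(overlaps))
    sd = float(np.std(overlaps, ddof=1))
    m_obs = g.number_of_edges()
    if sd == 0.0:
        logger.warning("null overlap has zero spread; z-score undefined")
        z = None
    else:
        z = z_score(m_obs, mean, sd)
    return NullModelSummary(
        model=model,
        n_replicates=n_replicates,
        m_observed=m_obs,
        overlaps=overlaps,
        mean_overlap=mean,
        sd_overlap=sd,
        z=z,
    )


def min_z(summaries: list[NullModelSummary]) -> float:
    """Smallest defined z-score across null models — the conservative
    non-randomness statistic."""
    zs = [s.z for s in summaries if s.z is not None]
    if not zs:
        raise ValueError("no summary has a defined z-score")
    return min(zs)
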