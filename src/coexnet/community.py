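"""Modularity, Louvain community detection, and hypergeometric gene-set enrichment.

Louvain is implemented here directly (rather than delegated) so that node
visiting order, tie-breaking and termination are fully specified and seeded:
given the same graph and seed the partition is reproducible bit-for-bit.
Modularity is the unweighted Newman quantity

    Q = sum_c [ l_c / m  -  (d_c / 2m)^2 ]

with ``l_c`` the number of intra-community edges, ``d_c`` the summed degree of
community ``c`` and ``m`` the total edge count.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

_TOL = 1e-7  # stop when a full level improves Q by less than this


@dataclass
class ModulePartition:
    """A gene-to-community assignment together with its modularity Q."""

    labels: dict[Hashable, int]
    q: float

    @property
    def sizes(self) -> dict[int, int]:
        return dict(Counter(self.labels.values()))

    def communities(self) -> dict[int, set[Hashable]]:
        out: dict[int, set[Hashable]] = defaultdict(set)
        for node, c in self.labels.items():
            out[c].add(node)
        return dict(out)


def modularity(g: nx.Graph, partition: Mapping[Hashable, int]) -> float:
    """Newman modularity of a node partition (unweighted edges)."""
    uncovered = [v for v in g.nodes if v not in partition]
    if uncovered:
        raise ValueError(f"partition does not cover node(s): {uncovered[:10]}")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    intra: Counter = Counter()
    deg: Counter = Counter()
    for u, v in g.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] += 1
    for v, d in g.degree():
        deg[partition[v]] += d
    return sum(intra[c] / m - (deg[c] / (2.0 * m)) ** 2 for c in deg)


def _one_level(
    adj: dict[int, dict[int, float]],
    m: float,
    rng: random.Random,
) -> tuple[dict[int, int], bool]:
    """One local-moving phase.  ``adj[u][u]`` holds the self-loop weight (counted
    once in the dict; it contributes twice to the degree).  Returns the node ->
    community map and whether any move happened."""
    nodes = sorted(adj)
    comm = {u: u for u in nodes}
    k = {u: sum(w for v, w in adj[u].items() if v != u) + 2.0 * adj[u].get(u, 0.0) for u in nodes}
    sigma_tot: dict[int, float] = defaultdict(float)
    for u in nodes:
        sigma_tot[comm[u]] += k[u]
    moved_any = False
    improved = True
    while improved:
        improved = False
        order = nodes[:]
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            weights_to: dict[int, float] = defaultdict(float)
            for v, w in adj[u].items():
                if v != u:
                    weights_to[comm[v]] += w
            sigma_tot[cu] -= k[u]
            # Gain of placing u (now isolated) into community c.
            best_c = cu
            best_gain = weights_to.get(cu, 0.0) - sigma_tot[cu] * k[u] / (2.0 * m)
            for c in sorted(weights_to):
                if c == cu:
                    continue
                gain = weights_to[c] - sigma_tot[c] * k[u] / (2.0 * m)
                # Strict improvement required: ties keep the current community,
                # and among tied neighbors the lowest label (visited first) wins.
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            sigma_tot[best_c] += k[u]
            if best_c != cu:
                comm[u] = best_c
                improved = True
                moved_any = True
    return comm, moved_any


def _aggregate(
    adj: dict[int, dict[int, float]],
    comm: Mapping[int, int],
) -> dict[int, dict[int, float]]:
    relabel = {c: i for i, c in enumerate(sorted(set(comm.values())))}
    new: dict[int, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for u, nbrs in adj.items():
        cu = relabel[comm[u]]
        for v, w in nbrs.items():
            cv = relabel[comm[v]]
            if u == v:
                new[cu][cu] += w  # self-loop weight carried over once
            elif u < v:
                if cu == cv:
                    new[cu][cu] += w
                else:
                    new[cu][cv] += w
                    new[cv][cu] += w
    return {u: dict(nbrs) for u, nbrs in new.items()}


def louvain(g: nx.Graph, seed: int = 0) -> ModulePartition:
    """Greedy two-phase modularity optimization with a seeded node order.

    Phase one visits nodes in seeded random order and moves each to the
    neighboring community with the largest positive modularity gain until no
    move improves; phase two collapses communities into super-nodes (with
    self-loops holding intra-community weight) and repeats.  Iteration stops
    when a level improves Q by less than 1e-7.  The reported Q is recomputed
    from the flattened partition on the original graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    if g.number_of_edges() == 0:
        return ModulePartition(labels={v: i for i, v in enumerate(nodes)}, q=0.0)

    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    for u, v in g.edges:
        iu, iv = index[u], index[v]
        if iu == iv:
            continue  # self-loops are excluded by the network invariant
        adj[iu][iv] = adj[iu].get(iv, 0.0) + 1.0
        adj[iv][iu] = adj[iv].get(iu, 0.0) + 1.0
    m = float(g.number_of_edges())

    rng = random.Random(seed)
    assignment = {i: i for i in range(len(nodes))}  # original node -> super-node
    q_prev = None
    while True:
        comm, moved = _one_level(adj, m, rng)
        relabel = {c: i for i, c in enumerate(sorted(set(comm.values())))}
        assignment = {v: relabel[comm[assignment[v]]] for v in assignment}
        partition = {nodes[i]: c for i, c in assignment.items()}
        q = modularity(g, partition)
        if not moved or (q_prev is not None and q - q_prev < _TOL):
            break
        q_prev = q
        adj = _aggregate(adj, comm)
    # Compact labels to 0..k-1 in order of first appearance over sorted nodes.
    final = {c: i for i, c in enumerate(dict.fromkeys(assignment[index[v]] for v in nodes))}
    labels = {v: final[assignment[index[v]]] for v in nodes}
    return ModulePartition(labels=labels, q=modularity(g, labels))


ENRICH_COLUMNS = ["cluster", "term_id", "term_name", "N", "K", "n", "k", "p", "p_adj"]


def hypergeom_enrich(
    clusters: ModulePartition,
    sets: GeneSetCollection,
    background: set[str],
    min_cluster_size: int = 20,
) -> pd.DataFrame:
    """Hypergeometric (upper-tail) gene-set enrichment of clusters.

    For a cluster of ``n`` genes and a term with ``K`` genes inside the
    ``N``-gene background, the p-value is ``P(X >= k)`` for the observed
    overlap ``k`` under the hypergeometric null.  Term gene sets are
    intersected with the background before counting; only clusters with at
    least ``min_cluster_size`` genes are tested; rows are sorted by p and a
    Benjamini-Hochberg adjusted column is added across all tests.
    """
    if not background:
        raise ValueError("empty background gene set")
    outside = {v for v in clusters.labels if v not in background}
    if outside:
        raise ValueError(f"cluster gene(s) missing from background: {sorted(outside)[:10]}")
    n_bg = len(background)
    rows = []
    for label, members in sorted(clusters.communities().items()):
        if len(members) < min_cluster_size:
            continue
        n = len(members)
        for term, (name, genes) in sets.items():
            term_genes = genes & background
            if not term_genes:
                continue
            big_k = len(term_genes)
            k = len(members & term_genes)
            p = float(hypergeom.sf(k - 1, n_bg, big_k, n))
            rows.append((label, term, name, n_bg, big_k, n, k, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table
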