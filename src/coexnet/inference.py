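"""Co-expression network inference: Pearson correlation, cutoff scan, graph construction.

Gene pairs whose expression vectors correlate at or above an absolute Pearson
cutoff become edges of an undirected network; the signed correlation is stored
as the edge weight, and genes without any passing edge are excluded.  A scan
of cutoffs between 0.5 and 1.0 records node/edge/component counts, density and
the modularity of a Louvain partition at each cutoff, from which a working
cutoff is selected as the most modular network that still retains a reasonable
fraction of genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["cutoff", "n_nodes", "n_edges", "n_components", "density", "modularity"]


def pearson_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation matrix.

    Requires at least 3 samples.  Genes with zero variance across samples are
    dropped (with a logged warning) rather than producing undefined
    correlations.
    """
    if matrix.n_samples < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {matrix.n_samples}")
    values = matrix.values.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0.0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped[:10])
        values = values[keep]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    corr = np.atleast_2d(np.corrcoef(values))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def build_network(corr: pd.DataFrame, cutoff: float) -> nx.Graph:
    """Threshold the correlation matrix into a co-expression network.

    An edge connects genes ``i`` and ``j`` iff ``|r_ij| >= cutoff`` (i != j);
    its weight is the signed correlation.  Nodes are exactly the genes with at
    least one passing edge.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    genes = list(corr.index)
    values = corr.to_numpy(dtype=float)
    rows, cols = np.nonzero(np.triu(np.abs(values) >= cutoff, k=1))
    g = nx.Graph()
    for i, j in zip(rows.tolist(), cols.tolist()):
        g.add_edge(genes[i], genes[j], weight=float(values[i, j]))
    return g


def threshold_scan(
    corr: pd.DataFrame,
    tau_min: float = 0.5,
    tau_max: float = 1.0,
    step: float = 0.02,
    with_modularity: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep the cutoff grid and record network size and structure at each value.

    Returns one row per cutoff with node count (genes with >= 1 edge), edge
    count, connected components, density ``2E / (N (N - 1))`` and, when
    ``with_modularity`` is set, the modularity Q of a Louvain partition.
    Edge counts are non-increasing in the cutoff by construction.
    """
    from .community import louvain  # local import to avoid a module cycle

    if step <= 0 or tau_min <= 0 or tau_max > 1.0 or tau_min > tau_max:
        raise ValueError("invalid cutoff grid")
    grid = np.round(np.arange(tau_min, tau_max + step / 2.0, step), 10)
    rows = []
    for tau in grid:
        g = build_network(corr, float(tau))
        n, m = g.number_of_nodes(), g.number_of_edges()
        density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
        q = np.nan
        if with_modularity and m > 0:
            q = louvain(g, seed=seed).q
        rows.append(
            {
                "cutoff": float(tau),
                "n_nodes": n,
                "n_edges": m,
                "n_components": nx.number_connected_components(g),
                "density": density,
                "modularity": q,
            }
        )
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def select_cutoff(
    scan: pd.DataFrame,
    total_genes: int,
    min_node_fraction: float = 0.1,
) -> float:
    """Pick the cutoff that maximizes modularity while keeping enough genes.

    Among scan rows whose node count is at least ``min_node_fraction *
    total_genes``, returns the cutoff with the largest modularity Q; ties are
    broken toward the larger cutoff.  This operationalizes the "most modular
    while retaining a reasonable number of genes" selection rule.
    """
    if scan.empty:
        raise ValueError("empty cutoff scan")
    floor = min_node_fraction * total_genes
    admissible = scan[(scan["n_nodes"] >= floor) & scan["modularity"].notna()]
    if admissible.empty:
        raise ValueError(
            f"no cutoff keeps >= {floor:.0f} nodes; lower min_node_fraction "
            f"(currently {min_node_fraction})"
        )
    best = None
    for row in admissible.itertuples():
        if best is None or row.modularity > best.modularity or (
            row.modularity == best.modularity and row.cutoff > best.cutoff
        ):
            best = row
    return float(best.cutoff)


@dataclass
class InferenceResult:
    """Bundle of the scan table, the chosen cutoff, and the final network."""

    scan: pd.DataFrame
    cutoff: float
    network: nx.Graph


def infer_network(
    matrix: ExpressionMatrix,
    cutoff: float | str = "auto",
    tau_min: float = 0.5,
    tau_max: float = 1.0,
    step: float = 0.02,
    min_node_fraction: float = 0.1,
    seed: int = 0,
) -> InferenceResult:
    """End-to-end inference: correlation, cutoff scan, selection, network build.

    ``cutoff`` may be a number in (0, 1] or ``"auto"`` to select the most
    modular admissible cutoff from the scan.
    """
    corr = pearson_matrix(matrix)
    scan = threshold_scan(corr, tau_min, tau_max, step, with_modularity=True, seed=seed)
    if cutoff == "auto":
        tau = select_cutoff(scan, total_genes=len(corr), min_node_fraction=min_node_fraction)
    else:
        tau = float(cutoff)
    return InferenceResult(scan=scan, cutoff=tau, network=build_network(corr, tau))
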