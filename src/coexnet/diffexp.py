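"""Two-group differential expression, network overlay, and the CREB-target filter.

Differential expression is the classic equal-variance two-sample Student
t-test per gene (tumor mean minus normal mean), two-sided, with significance
called at an uncorrected ``p <= alpha`` to match the conventions of
small-cohort microarray studies; a Benjamini-Hochberg column is also emitted
for modern use.  Significant genes are partitioned into up/down by the sign of
t.  Up-regulated genes can then be filtered against a CREB-target annotation
table: a gene is a putative cAMP-response element when its binding value
satisfies BV <= 0.001 and its binding ratio BR >= 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

DE_COLUMNS = ["gene", "t", "p", "p_adj", "significant", "direction"]


def ttest_de(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between tumor and normal samples.

    The t statistic is signed tumor-minus-normal; p-values are two-sided from
    the t distribution with ``n1 + n2 - 2`` degrees of freedom (Welch's
    correction available via ``equal_var=False``).  Genes with zero pooled
    variance get an undefined (NaN) p and are never called significant.
    """
    tumor = matrix.samples_in("tumor")
    normal = matrix.samples_in("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per group (tumor: {len(tumor)}, normal: {len(normal)})"
        )
    x = matrix.values[tumor].to_numpy(dtype=float)
    y = matrix.values[normal].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    table = pd.DataFrame({"gene": matrix.gene_ids, "t": t, "p": p})
    p_adj = np.full(len(table), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table["p_adj"] = p_adj
    table["significant"] = ok & (p <= alpha)
    direction = np.where(table["significant"] & (t > 0), "up", "")
    direction = np.where(table["significant"] & (t < 0), "down", direction)
    table["direction"] = pd.Series(direction).replace("", pd.NA)
    return table


class DeCounts(NamedTuple):
    n_up: int
    n_down: int
    n_total: int
    fraction: float


def de_counts(table: pd.DataFrame, background_size: int | None = None) -> DeCounts:
    """Up/down/total counts of significant genes and the fraction of the background.

    ``background_size`` defaults to the number of tested genes; pass the
    network gene count to express the fraction relative to network membership.
    """
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    total = n_up + n_down
    background = background_size if background_size is not None else len(table)
    fraction = total / background if background else 0.0
    return DeCounts(n_up=n_up, n_down=n_down, n_total=total, fraction=fraction)


def overlay_on_network(
    g: nx.Graph,
    table: pd.DataFrame,
    mutated_genes: Iterable[str] = (),
    partition: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Annotate network nodes with DE calls, mutated-gene membership and community.

    Returns a per-node table plus a summary with counts and nearest-percent
    shares of DE and mutated genes among network nodes.
    """
    mutated = set(mutated_genes)
    by_gene = table.set_index("gene")
    nodes = sorted(g.nodes)
    rows = []
    for v in nodes:
        if v in by_gene.index:
            sig = bool(by_gene.at[v, "significant"])
            direction = by_gene.at[v, "direction"] if sig else pd.NA
        else:
            sig, direction = False, pd.NA
        rows.append(
            {
                "gene": v,
                "degree": g.degree(v),
                "de": sig,
                "direction": direction,
                "mutated": v in mutated,
                "community": partition.get(v) if partition else pd.NA,
            }
        )
    node_table = pd.DataFrame(rows)
    n = len(nodes)
    n_de = int(node_table["de"].sum())
    n_mut = int(node_table["mutated"].sum())
    summary = {
        "n_nodes": n,
        "n_de": n_de,
        "pct_de": round(100.0 * n_de / n) if n else 0,
        "n_mutated": n_mut,
        "pct_mutated": round(100.0 * n_mut / n) if n else 0,
    }
    return node_table, summary


@dataclass
class CreFilterResult:
    """Outcome of filtering up-regulated genes against CREB-target annotation."""

    input_genes: list[str]
    annotated: list[str]
    passing: list[str]
    n_unannotated: int
    bv_max: float
    br_min: float
    strict: bool


def cre_filter(
    up_genes: Iterable[str],
    cre_table: pd.DataFrame,
    bv_max: float = 0.001,
    br_min: float = 1.5,
    strict: bool = False,
) -> CreFilterResult:
    """Select putative cAMP-response elements among up-regulated genes.

    A gene passes iff it is annotated in the table and its binding value and
    binding ratio clear the thresholds — inclusively (BV <= bv_max, BR >=
    br_min) by default, strictly (BV < bv_max, BR > br_min) with
    ``strict=True``.  Unannotated genes are excluded silently but counted.
    """
    up = sorted(set(up_genes))
    annot = cre_table.set_index("gene")
    annotated = [g for g in up if g in annot.index]
    passing = []
    for g in annotated:
        bv, br = float(annot.at[g, "bv"]), float(annot.at[g, "br"])
        if strict:
            ok = bv < bv_max and br > br_min
        else:
            ok = bv <= bv_max and br >= br_min
        if ok:
            passing.append(g)
    return CreFilterResult(
        input_genes=up,
        annotated=annotated,
        passing=passing,
        n_unannotated=len(up) - len(annotated),
        bv_max=bv_max,
        br_min=br_min,
        strict=strict,
    )
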