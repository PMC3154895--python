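import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import (
    ExpressionMatrix,
    default_paper_shape,
    infer_network,
    louvain,
    simulate,
)


def make_matrix(values, genes, samples, groups):
    """Small helper: ExpressionMatrix from nested lists."""
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples, dtype=float),
        groups=pd.Series(groups, index=samples),
    )


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, 2 tumor + 2 normal."""
    return make_matrix(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [4.0, 3.0, 2.0, 1.0]],
        genes=["GA", "GB", "GC"],
        samples=["s1", "s2", "s3", "s4"],
        groups=["tumor", "tumor", "normal", "normal"],
    )


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 0.95), ("b", "c", 0.96), ("a", "c", -0.97)])
    return g


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by a single bridge edge c-d."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )
    return g


@pytest.fixture(scope="session")
def paper_shape_run():
    """One study-shaped synthetic cohort analyzed end to end (shared across tests)."""
    config = default_paper_shape(seed=11)
    matrix, truth, gene_sets, cre_table = simulate(config)
    result = infer_network(matrix, cutoff="auto", seed=11)
    partition = louvain(result.network, seed=11)
    return {
        "config": config,
        "matrix": matrix,
        "truth": truth,
        "gene_sets": gene_sets,
        "cre_table": cre_table,
        "inference": result,
        "partition": partition,
    }
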