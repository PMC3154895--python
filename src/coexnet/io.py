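"""Validated containers and tab-delimited readers/writers shared by all pipeline stages.

File conventions: everything is UTF-8, tab-delimited, with ``#`` comment lines
ignored.  Expression matrices carry genes in rows and samples in columns; the
sample-metadata table assigns each sample to the ``tumor`` or ``normal`` group.
Gene symbols are treated as opaque text — no identifier translation happens
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("tumor", "normal")

_READ_KW = dict(sep="\t", comment="#")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample intensity matrix with a tumor/normal group label per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.  Values
        must be finite floats; missing values are rejected rather than imputed
        because Pearson correlations on a handful of samples are fragile to
        imputation.
    groups
        Series mapping every sample identifier to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicated gene identifier(s): {sorted(set(dup))}")
        dup_s = self.values.columns[self.values.columns.duplicated()]
        if len(dup_s):
            raise ValueError(f"duplicated sample identifier(s): {sorted(set(dup_s))}")
        if self.values.isna().any().any():
            gene, sample = self._first_missing()
            raise ValueError(f"missing value at gene {gene!r}, sample {sample!r}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"sample(s) without a group assignment: {missing}")
        bad = sorted(set(self.groups.loc[list(self.values.columns)]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group label(s) {bad}; expected one of {GROUPS}")
        self.groups = self.groups.loc[list(self.values.columns)]
        self.values = self.values.astype(float)

    def _first_missing(self) -> tuple[str, str]:
        mask = self.values.isna()
        for sample in mask.columns:
            col = mask[sample]
            if col.any():
                return str(col.idxmax()), str(sample)
        raise AssertionError("no missing value found")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO-BP terms or planted-module truth) keyed by term id."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def name(self, term: str) -> str:
        return self.sets[term][0]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def load_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV plus its sample metadata into an :class:`ExpressionMatrix`.

    The matrix file has a header row of sample identifiers and gene symbols in
    the first column; the metadata file has columns ``sample_id`` and
    ``group``.  Row and column order is preserved exactly as on disk.

    With ``log2=True`` intensities are transformed to ``log2(x + 1)`` after
    loading; by default values are used as given.
    """
    raw = pd.read_csv(matrix_path, index_col=0, dtype=str, **_READ_KW)
    raw.index = raw.index.astype(str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any().any():
        for sample in bad.columns:
            if bad[sample].any():
                gene = bad[sample].idxmax()
                raise ValueError(
                    f"non-numeric value {raw.at[gene, sample]!r} at gene {gene!r}, "
                    f"sample {sample!r} in {matrix_path}"
                )
    meta = pd.read_csv(metadata_path, dtype=str, **_READ_KW)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata {metadata_path} lacks required column {col!r}")
    groups = pd.Series(meta["group"].values, index=meta["sample_id"].values)
    matrix = ExpressionMatrix(values=values, groups=groups)
    if log2:
        matrix.values = np.log2(matrix.values + 1.0)
    return matrix


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the expression matrix and its sample metadata as TSV files."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": [matrix.groups[s] for s in matrix.sample_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    probe_map: Mapping[str, str],
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene by per-sample median.

    Affymetrix-style arrays carry several probesets per gene; where multiple
    probes map to one gene each sample keeps the median of the probes' values
    (for an even probe count, the mean of the two central values).
    """
    unmapped = [p for p in probe_matrix.values.index if p not in probe_map]
    if unmapped:
        raise ValueError(f"probe(s) without a gene mapping: {unmapped}")
    gene_order: list[str] = []
    seen: set[str] = set()
    for probe in probe_matrix.values.index:
        g = probe_map[probe]
        if g not in seen:
            seen.add(g)
            gene_order.append(g)
    grouped = probe_matrix.values.groupby(
        probe_matrix.values.index.map(probe_map.__getitem__), sort=False
    ).median()
    grouped = grouped.loc[gene_order]
    grouped.index.name = probe_matrix.values.index.name
    return ExpressionMatrix(values=grouped, groups=probe_matrix.groups)


# -- edge lists ----------------------------------------------------------------

EDGE_HEADER = ("gene_a", "gene_b", "pcc")


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write a co-expression network as a three-column TSV (gene_a, gene_b, pcc).

    Weights are written with six decimals, which round-trips the graph exactly
    at that precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_HEADER) + "\n")
        for a, b, data in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.6f}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(fields) == EDGE_HEADER:
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, w = fields
            try:
                weight = float(w)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {w!r}") from exc
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            g.add_edge(a, b, weight=weight)
    return g


# -- gene sets -----------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB gene1 TAB gene2 ...``.

    Duplicate genes within a line are removed; a line with fewer than three
    fields, or whose gene list is empty after de-duplication, is rejected with
    its line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene list for term {term!r}")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, genes) in collection.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# -- CREB-target annotation ----------------------------------------------------


def read_cre_table(path: str | Path) -> pd.DataFrame:
    """Read a CREB-target annotation TSV with columns gene, bv, br.

    ``bv`` is the binding value (a p-value-like score in (0, 1]); ``br`` is the
    binding ratio (>= 0).  One row per gene.
    """
    table = pd.read_csv(path, **_READ_KW)
    for col in ("gene", "bv", "br"):
        if col not in table.columns:
            raise ValueError(f"CRE table {path} lacks required column {col!r}")
    return validate_cre_table(table[["gene", "bv", "br"]])


def validate_cre_table(table: pd.DataFrame) -> pd.DataFrame:
    dup = table["gene"][table["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene(s) in CRE table: {sorted(set(dup))}")
    if (table["bv"] <= 0).any():
        bad = table.loc[table["bv"] <= 0, "gene"].tolist()
        raise ValueError(f"binding value must be > 0; offending gene(s): {bad}")
    if (table["br"] < 0).any():
        bad = table.loc[table["br"] < 0, "gene"].tolist()
        raise ValueError(f"binding ratio must be >= 0; offending gene(s): {bad}")
    return table.reset_index(drop=True)


def write_cre_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_cre_table(table).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list (e.g. a mutated-gene catalogue)."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def probe_map_from_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column probe-to-gene map (probe_id TAB gene_id)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected probe_id TAB gene_id")
            probe, gene = fields
            if probe in mapping and mapping[probe] != gene:
                raise ValueError(f"{path}:{lineno}: probe {probe!r} maps to two genes")
            mapping[probe] = gene
    return mapping
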