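"""End-to-end orchestration: simulate/load -> infer -> topology -> modules ->
null models -> robustness -> differential expression -> CREB filter.

A single flat YAML config drives the run; one global seed yields per-stage
seeds by fixed offsets so stages can be re-run independently yet
reproducibly.  Every stage writes its outputs as TSV under the output
directory and contributes summary numbers to a key->value run report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community import hypergeom_enrich, louvain
from .diffexp import cre_filter, de_counts, overlay_on_network, ttest_de
from .inference import infer_network
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    load_expression,
    read_cre_table,
    read_gene_list,
    read_gmt,
    write_cre_table,
    write_edge_list,
    write_expression,
    write_gmt,
)
from .nullmodels import MODELS, min_z, null_summary
from .robustness import attack, error
from .simulate import SimulationConfig, simulate
from .topology import node_table, summarize

logger = logging.getLogger(__name__)

# Fixed per-stage seed offsets from the global seed.
SEED_OFFSETS = {"simulate": 0, "louvain": 1, "null": 2, "error": 3, "scan": 4}


@dataclass
class RunConfig:
    """Flat, human-editable configuration of a full pipeline run."""

    # Input: either a simulation block or paths to an expression matrix + metadata.
    simulate: bool = True
    expression: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    cre: str | None = None
    mutated_genes: str | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # Analysis thresholds (defaults follow the reference study design).
    cutoff: float | str = "auto"
    min_node_fraction: float = 0.1
    scan_step: float = 0.02
    alpha: float = 0.05
    bv_max: float = 0.001
    br_min: float = 1.5
    min_cluster_size: int = 20
    null_replicates: int = 200
    f_max: float = 0.2
    removal_step: float = 0.01
    error_trials: int = 20
    seed: int = 7

    def validate(self) -> None:
        if not self.simulate:
            for name, path in (("expression", self.expression), ("metadata", self.metadata)):
                if path is None:
                    raise ValueError(f"config requires {name!r} when simulate is false")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
        if self.cutoff != "auto":
            if not 0.0 < float(self.cutoff) <= 1.0:
                raise ValueError(f"cutoff must be 'auto' or in (0, 1], got {self.cutoff}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_keys = {f.name for f in fields(SimulationConfig)}
        run_keys = {f.name for f in fields(cls)} - {"sim"}
        sim_kwargs = {k: v for k, v in raw.items() if k in sim_keys}
        run_kwargs = {k: v for k, v in raw.items() if k in run_keys}
        unknown = set(raw) - sim_keys - run_keys
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "module_sizes" in sim_kwargs:
            sim_kwargs["module_sizes"] = tuple(sim_kwargs["module_sizes"])
        cfg = cls(sim=SimulationConfig(**sim_kwargs), **run_kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        sim = data.pop("sim")
        sim["module_sizes"] = list(sim["module_sizes"])
        data.update(sim)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed + SEED_OFFSETS[stage]) % (2**31)


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis and return the run report (also written to disk)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    report: dict[str, object] = {"coexnet_version": __version__, "seed": config.seed}

    # -- input stage -----------------------------------------------------------
    truth = None
    gene_sets: GeneSetCollection | None = None
    cre_table = None
    mutated: set[str] = set()
    if config.simulate:
        logger.info("simulating synthetic cohort (seed %d)", config.sim.seed)
        matrix, truth, gene_sets, cre_table = simulate(config.sim)
        write_expression(matrix, out / "expression.tsv", out / "metadata.tsv")
        truth.as_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        write_gmt(gene_sets, out / "modules.gmt")
        write_cre_table(cre_table, out / "cre.tsv")
    else:
        logger.info("loading expression from %s", config.expression)
        matrix = load_expression(config.expression, config.metadata)
        if config.gmt:
            gene_sets = read_gmt(config.gmt)
        if config.cre:
            cre_table = read_cre_table(config.cre)
    if config.mutated_genes:
        mutated = read_gene_list(config.mutated_genes)
    report["n_genes"] = matrix.n_genes
    report["n_samples"] = matrix.n_samples
    report["n_tumor"] = len(matrix.samples_in("tumor"))
    report["n_normal"] = len(matrix.samples_in("normal"))

    # -- network inference -----------------------------------------------------
    logger.info("inferring network (cutoff=%s)", config.cutoff)
    result = infer_network(
        matrix,
        cutoff=config.cutoff,
        step=config.scan_step,
        min_node_fraction=config.min_node_fraction,
        seed=_stage_seed(config, "scan"),
    )
    result.scan.to_csv(out / "scan.tsv", sep="\t", index=False)
    write_edge_list(result.network, out / "network.tsv")
    g = result.network
    report["selected_cutoff"] = result.cutoff
    report["n_network_nodes"] = g.number_of_nodes()
    report["n_network_edges"] = g.number_of_edges()
    if g.number_of_edges() == 0:
        raise RuntimeError("network inference produced an empty network; lower the cutoff")

    # -- topology ----------------------------------------------------------------
    logger.info("computing topology statistics")
    topo = summarize(g)
    node_table(topo, g).to_csv(out / "topology_genes.tsv", sep="\t", index=False)
    topo_rows = {
        "n_nodes": topo.n_nodes,
        "n_edges": topo.n_edges,
        "average_degree": topo.average_degree,
        "diameter": topo.diameter,
        "max_eccentricity": topo.max_eccentricity,
        "mean_clustering": topo.mean_clustering,
        "n_components": topo.n_components,
        "density": topo.density,
        "power_law_slope": topo.power_law.slope if topo.power_law else "",
        "power_law_r2": topo.power_law.r_squared if topo.power_law else "",
    }
    _write_kv(topo_rows, out / "topology_summary.tsv")
    report["average_degree"] = topo.average_degree
    report["diameter"] = topo.diameter

    # -- communities and enrichment ---------------------------------------------
    logger.info("clustering network (Louvain)")
    partition = louvain(g, seed=_stage_seed(config, "louvain"))
    clusters = pd.DataFrame(
        sorted(partition.labels.items()), columns=["gene", "community"]
    )
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    report["modularity_q"] = partition.q
    report["n_clusters"] = len(partition.sizes)
    report["n_clusters_over_floor"] = sum(
        1 for s in partition.sizes.values() if s >= config.min_cluster_size
    )
    if gene_sets is not None:
        enrich = hypergeom_enrich(
            partition, gene_sets, set(g.nodes), min_cluster_size=config.min_cluster_size
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["n_enrichment_tests"] = len(enrich)

    # -- null models ---------------------------------------------------------------
    logger.info("sampling %d null replicates per model", config.null_replicates)
    summaries = [
        null_summary(g, model, n_replicates=config.null_replicates, seed=_stage_seed(config, "null"))
        for model in MODELS
    ]
    null_rows = []
    overlap_rows = []
    for s in summaries:
        null_rows.append(
            {
                "model": s.model,
                "replicates": s.n_replicates,
                "m_observed": s.m_observed,
                "mean_overlap": s.mean_overlap,
                "sd_overlap": s.sd_overlap,
                "z": s.z if s.z is not None else "undefined",
            }
        )
        overlap_rows.extend({"model": s.model, "overlap": o} for o in s.overlaps)
    pd.DataFrame(null_rows).to_csv(out / "null_summary.tsv", sep="\t", index=False)
    pd.DataFrame(overlap_rows).to_csv(out / "null_overlaps.tsv", sep="\t", index=False)
    report["min_z"] = min_z(summaries)

    # -- robustness -------------------------------------------------------------
    logger.info("attack/error robustness curves")
    curves = pd.concat(
        [
            attack(g, f_max=config.f_max, step=config.removal_step),
            error(
                g,
                f_max=config.f_max,
                step=config.removal_step,
                seed=_stage_seed(config, "error"),
                n_trials=config.error_trials,
            ),
        ],
        ignore_index=True,
    )
    curves.to_csv(out / "robustness.tsv", sep="\t", index=False)

    # -- differential expression and CREB filter ---------------------------------
    logger.info("differential expression (alpha=%.3g)", config.alpha)
    de = ttest_de(matrix, alpha=config.alpha)
    de.to_csv(out / "de.tsv", sep="\t", index=False)
    network_de = de[de["gene"].isin(g.nodes)]
    counts = de_counts(network_de, background_size=g.number_of_nodes())
    report["n_de_up"] = counts.n_up
    report["n_de_down"] = counts.n_down
    report["n_de_total"] = counts.n_total
    report["de_fraction_pct"] = round(100.0 * counts.fraction)
    overlay, overlay_summary = overlay_on_network(g, de, mutated, partition.labels)
    overlay.to_csv(out / "overlay.tsv", sep="\t", index=False)
    report["pct_mutated"] = overlay_summary["pct_mutated"]
    if cre_table is not None:
        up_genes = de.loc[de["direction"] == "up", "gene"]
        hits = cre_filter(up_genes, cre_table, bv_max=config.bv_max, br_min=config.br_min)
        pd.DataFrame({"gene": hits.passing}).to_csv(out / "cre_hits.tsv", sep="\t", index=False)
        report["n_cre_input"] = len(hits.input_genes)
        report["n_cre_pass"] = len(hits.passing)

    report["wall_time_s"] = round(time.monotonic() - t0, 3)
    _write_kv(report, out / "report.tsv")
    logger.info("run complete in %.1fs", report["wall_time_s"])
    return report


def _write_kv(mapping: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        for key, value in mapping.items():
            fh.write(f"{key}\t{value}\n")
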