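# coexnet

Gene co-expression network inference and graph-topology analysis for small
two-group transcriptome cohorts — e.g. a handful of tumor biopsies profiled
against normal tissue on expression microarrays. The package is aimed at
computational biologists who want the classical "relevance network" analysis
as a reproducible, tested pipeline rather than a collection of one-off
scripts: build the network, characterize its topology, cluster it, test it
against random-graph nulls, probe its stability, and overlay differential
expression with a CREB-target filter.

## What it computes

Given a gene-by-sample intensity matrix with tumor/normal labels:

1. **Network inference.** Pairwise Pearson correlation r across samples;
   gene pairs with |r| ≥ τ become edges (signed weight, unweighted topology).
   A scan of τ from 0.5 to 1.0 records nodes, edges, components, density and
   the modularity Q of a Louvain partition at each cutoff; `--cutoff auto`
   selects the τ maximizing Q subject to keeping at least 10% of genes.
2. **Topology.** Degree distribution with a log–log OLS power-law fit
   (scale-free assessment), betweenness centrality, clustering coefficients,
   components, and the *diameter* in this literature's sense: the average
   shortest-path length over intra-component node pairs.
3. **Communities.** Seeded Louvain modularity optimization
   (Q = Σ_c [l_c/m − (d_c/2m)²]), then hypergeometric gene-set enrichment of
   each cluster against a GMT collection, with Benjamini–Hochberg adjustment.
4. **Null models.** Degree-preserving Maslov–Sneppen rewiring (4m successful
   double-edge swaps) and Erdős–Rényi G(n, m) ensembles; R = 200 replicates
   each, edge-overlap mean ± SD with the observed network, and the
   non-randomness statistic z = (m_obs − mean overlap) / SD, minimized across
   models.
5. **Robustness.** Diameter and largest-component curves under targeted
   removal of the most connected hubs (attack) vs uniformly random removal
   (error).
6. **Differential expression.** Equal-variance Student t-test per gene
   (tumor − normal), two-sided p, significance at uncorrected p ≤ 0.05, up- /
   down-regulated split, overlay onto the network (including membership in a
   user-supplied mutated-gene list), and a CREB-target filter keeping
   up-regulated genes with binding value BV ≤ 0.001 and binding ratio
   BR ≥ 1.5.

A synthetic-data module generates study-shaped cohorts (default: 500 genes —
ten 20-gene modules with 2 hub genes each plus 300 background genes — across
9 tumor and 4 normal samples) with planted module structure, mean-shifted
genes and matching truth files, so the whole pipeline is testable without any
external data. See `docs/methods.md` for the generative model and all
numerical conventions.

## Worked example

Simulate a cohort and run the stages individually (everything is also
available as one `coexnet run --config run.yaml --out DIR` call, and as plain
Python via `import coexnet`):

```sh
$ echo "seed: 11" > sim.yaml
$ coexnet simulate --config sim.yaml --out .
wrote synthetic cohort (500 genes x 13 samples) to .

$ coexnet infer --expr expression.tsv --meta metadata.tsv --cutoff auto \
    --scan-out scan.tsv --edges-out network.tsv --seed 11
cutoff=0.9: 287 nodes, 1024 edges

$ coexnet topology --edges network.tsv --out topo_genes.tsv --summary-out topo.tsv
287 nodes, 1024 edges, average degree 7.14, diameter 3.229

$ coexnet modules --edges network.tsv --gmt modules.gmt --seed 11 \
    --min-cluster-size 15 --out clusters.tsv --enrich-out enrichment.tsv
20 communities, Q=0.8944

$ coexnet null --edges network.tsv --reps 200 --seed 11 --out null.tsv
maslov_sneppen: mean overlap 69.0 (sd 6.8), z=141.5
erdos_renyi: mean overlap 25.9 (sd 4.9), z=202.8

$ coexnet de --expr expression.tsv --meta metadata.tsv --out de.tsv
144 significant genes (73 up, 71 down; 29% of 500)

$ coexnet cre --de de.tsv --cre cre.tsv --out cre_hits.tsv
46 of 73 up-regulated genes pass (BV<=0.001, BR>=1.5; 7 unannotated)
```

Reading the numbers: the scan settles on τ = 0.9, where the 287-gene network
is highly modular (Q ≈ 0.89). The 20 communities include the ten planted
modules recovered exactly — the enrichment table ranks each module's own gene
set first with overlap k = 20 of 20 (hypergeometric p ≈ 3.3e-31 against the
287-gene background):

```
cluster  term_id  term_name           N    K   n   k   p            p_adj
8        M06      planted module M06  287  20  20  20  3.33e-31     9.16e-30
9        M07      planted module M07  287  20  20  20  3.33e-31     9.16e-30
```

Both null ensembles share only a few dozen of the 1024 observed edges
(z ≥ 141, i.e. the network is far from random), and the t-test recovers the
planted 27% differentially expressed genes (144/500 ≈ 29% observed at
p ≤ 0.05, which includes the expected ~5% false positives), of which the
CREB-target filter keeps the planted 70% pass fraction among annotated
up-regulated genes.

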