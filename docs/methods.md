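# Methods

`coexnet` implements gene co-expression network inference and graph-topology
analysis for small two-group transcriptome cohorts, together with a synthetic
cohort generator that makes every stage testable end to end. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Network inference

Pairwise similarity between gene expression vectors is the sample Pearson
correlation coefficient (PCC), computed across all samples of both groups.
Genes with zero variance are dropped before correlation (their PCC is
undefined); at least 3 samples are required. Correlations are computed in
one shot with `numpy.corrcoef` and validated in tests against a two-pass
evaluation of the definition to 1e-12.

A cutoff `tau` in (0, 1] turns the correlation matrix into an undirected
network: gene pairs with `|r| >= tau` become edges, the signed correlation is
kept as the edge weight, and genes with no passing edge are excluded from the
node set. All downstream topology uses the unweighted skeleton; signs are
preserved only for reporting.

The cutoff scan sweeps `tau` from 0.5 to 1.0 in steps of 0.02 (configurable)
and records node count, edge count, connected components, density
`2E / (N (N - 1))`, and the modularity Q of a Louvain partition at each
cutoff. Automatic selection returns the cutoff maximizing Q among scan rows
that keep at least `min_node_fraction` (default 0.1) of the input genes,
breaking ties toward the larger cutoff. This formalizes the qualitative
"most modular while retaining a reasonable number of genes and links"
criterion as a constrained optimization: without the node floor, modularity
increases as the network fragments into ever-smaller components, so the floor
is what makes the maximization meaningful.

## Topology statistics

Degree, degree histogram, local clustering coefficient
(`2 * links_among_neighbors / (k (k - 1))`, zero below degree 2), betweenness
centrality (unnormalized shortest-path pair counts, equal-length ties split
equally), connected components and density follow standard definitions.

One domain convention deserves emphasis: throughout this package the network
**diameter is the average shortest-path length** over node pairs, restricted
to pairs inside the same connected component so it stays finite on fragmented
graphs. The classical longest-shortest-path diameter is exposed separately
as `max_eccentricity` to avoid confusion. Shortest paths are computed with
`scipy.sparse.csgraph` (unweighted BFS in compiled code); tests compare the
result to a pure-Python all-pairs BFS oracle on random graphs up to 30 nodes.

Scale-free character is assessed the classical way: ordinary least squares of
`log10(count)` on `log10(degree)` over nonzero histogram bins, reporting
slope, intercept and R². This matches how degree distributions of biological
networks were historically presented; maximum-likelihood power-law fitting
and formal hypothesis tests are out of scope.

## Community detection

Modularity is the unweighted Newman quantity
`Q = sum_c [ l_c/m − (d_c/2m)² ]`. Louvain is implemented in the package
(not delegated) so that every behavioral detail is pinned down and seeded:

* phase 1 visits nodes in a seeded random order and moves each node to the
  neighboring community with the largest strictly positive modularity gain;
  on ties the node keeps its current community, and among tied neighboring
  communities the lowest label wins;
* phase 2 collapses communities into super-nodes (self-loops carry
  intra-community weight) and phase 1 repeats on the aggregate;
* iteration stops when a full level improves Q by less than 1e-7;
* the reported Q is recomputed from the flattened partition on the original
  graph, so it is self-consistent by construction;
* resolution is fixed at 1 (the method is used as a parameter-free
  procedure).

On graphs small enough to enumerate every set partition, the implementation
attains the exhaustively verified optimum on the canonical toy cases (two
disjoint triangles, Q = 0.5; two triangles joined by a bridge, Q = 5/14) and
beats at least 95% of all partitions on random 8-node graphs. On a planted
clique-of-cliques graph it agrees with networkx's independent Louvain
implementation.

Cluster enrichment uses the hypergeometric upper tail: for a cluster of `n`
genes and a gene set with `K` members inside the `N`-gene background (all
network genes), the p-value is `P(X >= k)` for the observed overlap `k`,
computed with `scipy.stats.hypergeom.sf` and validated against exact
enumeration. Gene sets are intersected with the background before counting.
Only clusters with at least `min_cluster_size` genes (default 20) are tested.
Raw p-values are reported alongside a Benjamini–Hochberg adjusted column; the
uncorrected values preserve the historical behavior, the adjusted ones are
for modern use.

## Null models and non-randomness

Two null ensembles are compared with the observed network by edge overlap:

* **Maslov–Sneppen rewiring**: `4m` successful double-edge swaps
  ((a,b),(c,d) → (a,d),(c,b)); swaps creating self-loops or parallel edges
  are rejected and do not count, so the intended mixing is achieved
  regardless of the rejection rate. An attempt cap (100× the swap budget)
  guarantees termination on graphs with no valid swap (a triangle is returned
  unchanged). Degree sequences are preserved exactly.
* **Erdős–Rényi G(n, m)**: the original node set with exactly `m` edges
  drawn uniformly without replacement from all node pairs. Its expected
  overlap with the original graph is `m² / C(n, 2)`, which the implementation
  reproduces within Monte-Carlo error.

For each model, R replicates (default 200, per-replicate seeds derived
deterministically from one seed) yield the overlap mean and sample SD, and
the non-randomness statistic `z = (m_observed − mean_overlap) / sd_overlap`;
the minimum across models is the conservative summary. When the overlap
spread is zero (e.g. a complete graph under G(n, m)) the z is reported as
undefined rather than infinite.

A caveat worth stating plainly: because the expected overlap of a sparse
random graph with any fixed sparse graph is tiny, this z-score is enormous
for essentially *any* observed network, structured or not — it measures
distance from the null ensemble, not modularity. It is retained because it
is the established summary for this analysis; the planted-structure recovery
metrics, not z, are what demonstrate that the pipeline finds real structure.

## Robustness

Attack removes the currently highest-degree node (ties broken toward the
lowest label), re-ranking degrees after every removal by default (a static
ranking is available); error removes uniformly random nodes, averaged over
`n_trials` seeded trials (default 20). Curves record, at each point of a
removal-fraction grid (default 0 to 0.2 in steps of 0.01), the number of
nodes removed, the diameter (average-shortest-path convention), and the size
of the largest component. A graph with no surviving connected pair reports
diameter 0 with an explicit flag so curves remain plottable through collapse.

On hub-dominated graphs (preferential-attachment topology) the attack curve's
diameter at 5% removal exceeds the error curve's by a wide margin; on
degree-regular graphs, where attack has no hubs to exploit, the attack
diameter sits inside the Monte-Carlo spread of random removals.

## Differential expression and the CREB-target filter

Per-gene differential expression is the classic equal-variance two-sample
Student t-test (Welch available via a flag), signed tumor-minus-normal,
two-sided p from the t distribution with `n1 + n2 − 2` degrees of freedom.
Significance is called at uncorrected `p <= alpha` (default 0.05) to match
small-cohort microarray practice; a BH-adjusted column is always emitted.
Direction (up/down) is assigned from the sign of t among significant genes
only. Genes with zero pooled variance get an undefined p and are never
significant. Each group must contain at least 2 samples.

Up-regulated genes are filtered against a CREB-target annotation table
(binding value BV, binding ratio BR): a gene passes when `BV <= 0.001` and
`BR >= 1.5` (inclusive thresholds by default; strict inequalities via a
flag). Unannotated genes are excluded silently but counted. The filter is
monotone: tightening either threshold never adds a passing gene.

## Synthetic cohorts

The generator emulates a small two-group microarray study. Defaults define
the study conditions and are not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | total genes |
| `module_sizes` | 10 × 20 | planted co-expression modules |
| `background_genes` | 300 | pure-noise genes |
| `loading` (a) | 0.95 | gene loading on its module factor |
| `noise_sd` (σ) | 0.3 | residual SD per gene |
| `n_hubs_per_module` | 2 | genes also loading a/2 on the next module |
| `n_tumor`, `n_normal` | 9, 4 | two-group cohort shape |
| `de_fraction` | 0.27 | fraction of genes mean-shifted in tumor samples |
| `de_effect` (Δ) | 3 | shift in units of σ (= standardized effect size) |
| `cre_pass_fraction` | 0.7 | up-regulated genes passing the BV/BR filter |

Each module has a latent factor `f_c(s) ~ N(0,1)` i.i.d. across samples; a
module gene is `a·f_c + ε`, `ε ~ N(0, σ²)`, giving a within-module population
correlation `a²/(a² + σ²) ≈ 0.91` at the defaults. Hub genes additionally
load `a/2` on the next module (cyclically). Differentially expressed genes
are drawn uniformly **from the background pool** and shifted by `±Δ·σ` on all
tumor samples. Confining the shift to background genes is a deliberate
design choice: it leaves the planted module correlation untouched (so module
recovery and DE can be validated independently) and makes Δ exactly the
standardized effect size of the shifted genes, since a background gene's
marginal SD is σ. With Δ = 3 and 9-vs-4 samples the pooled t-test has ≈99%
power, and the type-I error rate at α = 0.05 is calibrated (checked against
binomial bounds on a 2000-gene null cohort).

Two emergent properties of the generative model are worth knowing when
reading test output. First, same-direction shifted genes share the group
indicator and therefore correlate (population `r ≈ 0.66` pooled across
groups, appearing as `|r|` for opposite directions), so shifted background
genes legitimately enter the network as their own small cliques at permissive
cutoffs. They are planted correlation, not error; recovery metrics (ARI,
enrichment top-1) are therefore evaluated over genes whose planted label is a
module. Second, since the within-module population correlation (0.91) lies
below 0.94, a hard 0.94 cutoff fragments 13-sample modules; recovery is
evaluated at the automatically selected cutoff (typically 0.88–0.92 on these
cohorts), which is also the pipeline default. For the recovery evaluation the
enrichment cluster-size floor is 15 rather than 20, because planted modules
have exactly 20 genes and the thresholded network drops a few per module.

What the synthetic experiments show: the full pipeline recovers planted
modules (ARI ≥ 0.9 over 10 cohorts), ranks each module's own gene set first
in enrichment, recovers ≥ 90% of shifted genes with correct direction, and
reproduces the analytic G(n, m) overlap expectation. What they do not show:
anything about probe-level artifacts, normalization, batch effects,
non-Gaussian expression noise, or correlation structures other than the
block-plus-hub model — real microarray data are messier on all counts, and a
cutoff appropriate for these synthetic cohorts is not automatically
appropriate for a real dataset.

## Degenerate inputs and numerical conventions

* Median collapsing of multi-probe genes uses the standard median (mean of
  the two central values for even counts).
* Expression values are used as given; `log2(x + 1)` is an opt-in flag on the
  loader. Missing values are rejected, not imputed — PCC on a dozen samples
  is fragile to imputation.
* Edge weights round-trip through TSV at 6 decimals.
* Louvain's level-gain tolerance is 1e-7; move-gain ties use an absolute
  1e-12 guard.
* Sample (n−1) SD everywhere a spread is reported.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from one global seed by fixed offsets, and
  replicate seeds via `numpy.random.SeedSequence`, so full runs are
  byte-reproducible apart from wall-clock fields.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run on 500-gene × 13-sample
cohorts (10 seeds), 2000-gene null cohorts for calibration, 200 null-model
replicates per ensemble (1000 for the analytic overlap check), 300-node
preferential-attachment graphs for the robustness contrast, and exhaustive
enumeration on graphs of up to 8 nodes (set partitions) or 30 nodes
(shortest-path oracles). These sizes give stable statistics at interactive
runtimes.
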