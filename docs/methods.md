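# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the relapsegrn pipeline, in the order the stages run.

## Differential expression

Counts are modelled as negative binomial with `Var(K) = μ + αμ²`.
Normalization is the median-of-ratios estimator: the reference is the
per-gene geometric mean across samples, restricted to genes with strictly
positive counts in every sample; sample factors are the medians of the
count/reference ratios (taken on the ratios themselves, not in log space —
the two differ for even gene counts), rescaled so their geometric mean is 1.
If no gene is positive everywhere the stage fails loudly rather than
falling back to a pseudo-reference.

The test is a Wald test on `log2FC = log2((μ̂_B + c)/(μ̂_A + c))` with
pseudocount `c = 0.5` guarding zero-mean groups. The gene-wise dispersion is
method-of-moments from the pooled within-group variance of normalized
counts, floored at 0; the delta-method standard error of each group's
log2 mean uses `(μ̂_k + αμ̂_k²)/n_k`. There is no shrinkage across genes, no
independent filtering and no outlier handling: the engine is deliberately
simple, and `de_results.tsv` doubles as an import format so results from a
full-featured external DE tool can be substituted for everything
downstream. Genes with all-zero counts in both groups are reported with
`log2FC = 0, p = 1`, never dropped. At the default study conditions
(5 vs 5, dispersion 0.1) the test is mildly anticonservative under the null
(type-I ≈ 0.07–0.09 at nominal 0.05), which the acceptance checks bound at
three times nominal; ranking quality is what the pipeline relies on
(AUROC > 0.99 for the planted 10% at |log2FC| = 2).

DEG thresholds are `padj ≤ 0.05` and `|log2FC| ≥ 1.5`, both boundaries
inclusive — the conservative reading of a "±1.5" cutoff. Functional-term
exclusion removes any DEG annotated to an excluded GO term or to any
descendant through both `is_a` and `part_of`, matching GO annotation
propagation convention; the operation is idempotent and reports the removed
genes.

## Over-representation core

`hypergeom_upper(k, K, n, N)` is the exact upper tail `P(X ≥ k)`
(scipy's hypergeometric survival function; verified in the test suite
against an integer-arithmetic combinatorial sum for every universe up to
N = 60 and against one-sided Fisher exact p-values). BH adjustment is the
literal step-up `q_(i) = min_{j≥i} p_(j)·m/j` clipped at 1, cross-checked
against statsmodels. Decisions a user should know:

- The universe is the set of genes tested for DE, not the genome.
- Categories with zero query overlap, or with fewer than 2 members in the
  universe (configurable), are skipped **before** BH, so `m` is the number
  of categories actually tested.
- miRNA target sets are not evidence-filtered before enrichment by default
  (the evidence filter belongs to network construction); a config switch
  (`filter_enrichment_evidence`) applies it earlier for users who want the
  stricter reading.

## Network construction and hotspots

Candidates are DEGs ∪ enriched miRNAs. An interaction enters the network
only if **both** endpoints are candidates (one-endpoint inclusion would pull
in entities the contrast never tested) and its evidence label equals the
required class ("experimental"). The same node pair may carry several typed
edges (e.g. a regulator acting both as TF and through a miRNA identifier);
they are kept distinct and each contributes to degree. Disease
contextualization keeps edges with at least one disease-associated endpoint
and drops isolated nodes; it is idempotent, and with every node associated
it is the identity.

Centralities: total (in+out) degree; betweenness on the directed simple
graph with raw pair counts (unnormalized); harmonic closeness and
eigenvector centrality on the undirected skeleton, both chosen because they
are well-defined on disconnected graphs. Eigenvector centrality is computed
by power iteration at tolerance 1e-10 (10,000-step cap) on the adjacency
plus identity — the spectral shift leaves the principal eigenvector
unchanged while preventing oscillation on bipartite components.

Hotspots: per measure, the cutoff rank is `⌈f·n⌉` with `f = 0.10` and every
node tied with the cutoff score is selected; the hotspot set is the union
over the four measures, applied to genes and miRNAs jointly (a per-kind
switch exists). Tie inclusiveness makes the rule deterministic without
arbitrary ordering, with a consequence worth knowing: on small two-layer
regulatory networks most nodes have betweenness exactly 0, the cutoff score
is then 0, and that measure selects everything — the union is the whole
network. The per-measure rankings remain informative, and the behaviour
disappears on networks deep enough to have interior nodes.

## Semantic similarity and the homogeneity test

Wang's measure with the customary weights (`is_a` 0.8, `part_of` 0.6) was
chosen because it needs no annotation corpus (information-content measures
do) and is fully deterministic given the DAG; gene-level similarity is the
best-match average. Cross-namespace term pairs score 0 by definition. The
default namespace is biological_process. S-values are computed by dynamic
programming over the ancestor subgraph in topological order and cached per
DAG instance.

The homogeneity test asks whether a network's gene set is functionally
tighter than chance: pairwise BMA scores of the set versus scores pooled
over 100 random same-size sets drawn without replacement from the annotated
universe (an annotation-count-matched drawing mode is available). The
one-sided two-sample KS statistic D⁻ captures "stochastically greater".
The **reported p-value is empirical**: the rank of the observed D⁻ among
the D⁻ of the 100 random sets themselves (smallest attainable p = 1/101).
The classical KS p against the pooled null (exact when both samples ≤ 25
values, asymptotic otherwise) is reported alongside as
`pvalue_asymptotic`, but it treats the ~m(m−1)/2 pairwise scores of an
m-gene set as independent when they share genes; a 200-replicate null
calibration showed it rejects ~13.5% of random sets at nominal 5%, while
the empirical p rejects ~5–6%. Across contrasts the empirical p-values are
BH-adjusted jointly.

## Synthetic study design

The generators emulate the statistical structure of a multi-contrast
relapse experiment; all are pure functions of their arguments including the
seed, with one master seed feeding independent per-generator streams
(`numpy` `SeedSequence` spawning) so stages can be re-run alone.

- **Counts**: baseline means log-normal(log 100, 1) — a typical RNA-seq
  abundance spread — NB dispersion 0.1, 5 biological replicates per group,
  2000 genes, 10% DE with the group-B mean multiplied by `2^±2` (random
  sign, constant magnitude).
- **Regulatory DB**: 80 TFs (drawn from the gene universe — TFs are genes,
  and 80/2000 mirrors genome-wide TF proportions), 40 miRNAs, 25 targets
  per regulator, all four edge classes, 70% experimental evidence. One
  planted miRNA per contrast draws 80% of its targets from that contrast's
  DE genes; one planted driver hub per contrast (a well-expressed DE gene
  whose realized count ratio reflects the planted effect — a silent plant
  would defeat the recovery tests) gains experimental TF edges to 30% of
  its contrast's DE genes.
- **Disease list**: each entity associated independently with probability
  0.4, plus all planted regulators (contextualization must not sever the
  planted structure).
- **GO**: a complete 3-ary tree of depth 4 (121 terms) with 10% part_of
  shortcut edges toward shallower terms (acyclicity by construction);
  background genes annotated to 1–2 uniform-random leaves, each contrast's
  DE genes annotated to leaves under one depth-1 anchor, which makes each
  network's gene set homogeneous by construction.

What the generators do **not** emulate: library-size variation beyond the
NB noise (size factors come out near 1), gene–gene expression correlation,
batch effects, hub-degree distributions of real regulatory databases, GO's
true depth/breadth and shared multi-parent structure, or identifier
harmonization (IDs are opaque strings). Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
structure under idealized conditions, not performance on real data.

## Problem sizes

The default study uses two contrasts of 2000 genes × (5+5) samples, ~3300
regulatory interactions, 121 GO terms and 100 random sets per homogeneity
test; the calibration experiments use 200 replicates. These sizes keep the
full test suite and the acceptance script to a few minutes while leaving
every statistical check well-powered.

## Known limitations

- The DE engine's dispersion estimate is per-gene method-of-moments; at
  2–3 replicates it is noisy and the Wald p-values are approximate.
- The empirical homogeneity p is bounded below by 1/(n_random_sets+1);
  raise `n_random_sets` for finer resolution.
- Hotspot selection degenerates to all nodes whenever a centrality measure
  is constant (see above).
- The pipeline treats contrasts independently; it does not model shared
  controls or paired designs.
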