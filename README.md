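# relapsegrn

Inference of relapse-associated gene-regulatory networks from two-group
RNA-seq contrasts, for systems biologists studying how tumour cells
reprogram their regulation after a chemotherapeutic agent is withdrawn
(e.g. B-ALL cell lines after release from cytarabine or dexamethasone
pressure). Given a count matrix per contrast, a typed regulatory-interaction
database (TF→gene, TF→miRNA, miRNA→gene, miRNA→miRNA with evidence labels),
a disease-association list, and a GO DAG with annotations, the pipeline:

1. **Differential expression** — median-of-ratios normalization
   (`s_j = median_g k_gj / (∏_j k_gj)^{1/m}` over genes positive in all
   samples, rescaled to geometric mean 1) followed by a negative-binomial
   Wald test: per gene, `log2FC = log2((μ̂_B + c)/(μ̂_A + c))` with
   `c = 0.5`, standard error from `Var(K) = μ + αμ²` with a
   method-of-moments dispersion `α̂ = max(0, (s² − μ̂)/μ̂²)`, and
   Benjamini–Hochberg adjustment. DEGs are called at `padj ≤ 0.05` and
   `|log2FC| ≥ 1.5` (both inclusive), with optional exclusion of genes
   annotated under confounding GO branches (stress response, metabolism).
2. **miRNA-target enrichment** — for each miRNA with targets among the
   tested genes, the hypergeometric upper tail
   `P(X ≥ k), X ~ Hypergeom(N, K, n)` of the overlap between its target set
   and the DEG list (equivalently a one-sided Fisher exact test), BH across
   tested miRNAs at FDR 5%.
3. **Network construction** — co-regulatory network over DEGs ∪ enriched
   miRNAs keeping only interactions with both endpoints in that candidate
   set and experimental evidence, then contextualized to the disease by
   retaining edges with at least one disease-associated endpoint.
4. **Hotspots** — per centrality measure (total degree, directed
   shortest-path betweenness, harmonic closeness and eigenvector centrality
   on the undirected skeleton) the top `⌈0.10 · n⌉` nodes (ties at the
   cutoff included); the hotspot set is the union over the four measures.
5. **Semantic validation** — pairwise gene functional similarity by Wang's
   measure (`S_A(A)=1`, `S_A(t) = max_child w·S_A(child)` with `w = 0.8`
   for is_a, `0.6` for part_of;
   `sim = Σ_{t∈anc(A)∩anc(B)}(S_A(t)+S_B(t)) / (SV(A)+SV(B))`) combined by
   best-match average, tested against 100 same-size random gene sets with a
   one-sided two-sample Kolmogorov–Smirnov statistic; the p-value is the
   empirical rank of the observed statistic in the random-set ensemble, and
   BH is applied across contrasts.

Because real regulatory databases and ontologies are large moving targets,
the package ships seeded generators (`relapsegrn.simulate`) that produce
every input with planted ground truth — DE genes, an enriched miRNA and a
driver hub per contrast, and a functionally homogeneous GO module — so each
stage's recovery and calibration can be tested end to end.

## Worked example

The numbered scripts under `analysis/` run the study on the default
synthetic preset (two contrasts, 2000 genes, 5 vs 5 samples, 10% DE at
|log2FC| = 2, NB dispersion 0.1). `python analysis/05_semantic_validation.py`
prints:

```
   contrast  ks_statistic   pvalue  pvalue_asymptotic     padj  significant
lineA-drugX      0.520032 0.009901       0.000000e+00 0.009901         True
lineA-drugY      0.302766 0.009901      5.473797e-208 0.009901         True
lineA-drugX: 187 DEGs -> 1 miRNAs -> 72-node network -> 72 hotspots; homogeneity KS=0.520
lineA-drugY: 187 DEGs -> 1 miRNAs -> 74-node network -> 74 hotspots; homogeneity KS=0.303
```

Reading this: each contrast calls ~187 of its 200 planted DE genes
(precision 1.0, recall 0.94 — see `analysis/02`), the single planted miRNA
is the only one passing FDR 5% (rank 1 of ~40 tested, `analysis/03`), the
evidence- and disease-filtered network contains the planted driver hub with
the top degree (`analysis/04`), and the network genes are far more
functionally similar than random gene sets (KS statistic 0.30–0.52; the
empirical p of 1/101 is the smallest value 100 random sets can resolve).
On these small sparse networks betweenness is zero for almost every node,
so its tie-inclusive top-10% selection admits all nodes and the hotspot
union degenerates to the whole network — the per-measure rankings (degree,
eigenvector) are the informative ones there.

The same stages are available as a CLI (`relapsegrn simulate | de |
enrich-mirna | grn | hotspots | semsim | run`) over TSV/GMT/SIF files.

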