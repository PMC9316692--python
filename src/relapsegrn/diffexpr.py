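"""Differential expression between two conditions on NB count data.

Normalization is DESeq-style median-of-ratios. The test is a Wald test on
the log2 fold change of normalized group means with a method-of-moments
gene-wise NB dispersion (no shrinkage): a deliberately simple engine whose
output table doubles as an import format, so externally produced DE results
can be substituted for any downstream stage.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import CountMatrix, DEGSet
from .enrichment import bh_adjust
from .ontology import AnnotationMap, GoDag

DE_COLUMNS = ["baseMeanA", "baseMeanB", "log2FC", "pvalue", "padj"]

#: pseudocount added to group means before taking log2 fold changes
PSEUDOCOUNT = 0.5


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    For each sample j, the factor is the median over genes (restricted to
    genes with positive counts in every sample) of count_gj divided by the
    gene's geometric mean across samples. Factors are then rescaled so their
    geometric mean is 1, which makes equal columns map to factors of 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    sub = vals[all_pos]
    geomean = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / geomean[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def nb_wald_test(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A on normalized counts.

    log2FC = log2((meanB + c) / (meanA + c)) with pseudocount c. The Wald
    standard error uses the NB variance mu + alpha mu^2 with a gene-wise
    method-of-moments dispersion alpha (pooled within-group variance,
    floored at 0). Genes with all-zero counts in both groups are reported
    with log2FC 0 and p 1, not dropped. padj is Benjamini-Hochberg.
    """
    if factors is None:
        factors = size_factors(cm)
    factors = factors.reindex(cm.sample_ids)
    q = cm.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    lev_a, lev_b = cm.group_levels
    idx_a = [cm.sample_ids.index(s) for s in cm.samples_of(lev_a)]
    idx_b = [cm.sample_ids.index(s) for s in cm.samples_of(lev_b)]
    qa, qb = q[:, idx_a], q[:, idx_b]
    na, nb = qa.shape[1], qb.shape[1]
    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)

    c = PSEUDOCOUNT
    log2fc = np.log2((mean_b + c) / (mean_a + c))

    # method-of-moments dispersion from pooled within-group variance
    var_a = qa.var(axis=1, ddof=1)
    var_b = qb.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    overall_mean = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - overall_mean) / overall_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, 0.0)

    # delta-method SE of log2(mean + c) per group, NB variance of the mean
    var_mean_a = (mean_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b + alpha * mean_b**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_mean_a / ((mean_a + c) * ln2) ** 2 + var_mean_b / ((mean_b + c) * ln2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    both_zero = (mean_a == 0) & (mean_b == 0)
    log2fc[both_zero] = 0.0
    pvalue[both_zero] = 1.0
    pvalue = np.clip(pvalue, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2FC": log2fc,
            "pvalue": pvalue,
        },
        index=pd.Index(cm.gene_ids, name="gene"),
    )
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def call_degs(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    provenance: tuple[str, ...] = (),
) -> DEGSet:
    """Threshold a DE table into a DEG set: padj <= alpha and |log2FC| >= t.

    Both boundaries are inclusive. Direction is the sign of log2FC.
    """
    cfg = cfg or PipelineConfig()
    if "padj" not in table.columns:
        raise ValueError("DE table has no padj column")
    keep = (table["padj"] <= cfg.fdr_alpha) & (
        table["log2FC"].abs() >= cfg.lfc_threshold
    )
    genes = set(table.index[keep])
    direction = {
        g: (1 if table.at[g, "log2FC"] >= 0 else -1) for g in genes
    }
    return DEGSet(genes=genes, direction=direction, provenance=provenance)


def filter_functional_terms(
    degs: DEGSet,
    annot: AnnotationMap,
    dag: GoDag,
    excluded_terms: Iterable[str],
) -> tuple[DEGSet, list[str]]:
    """Drop DEGs annotated to any excluded term or its descendants.

    Emulates filtering out genes tied to confounding functional categories
    (e.g. stress response, metabolism) so downstream stages focus on
    relapse-associated genes. Exclusion propagates through both is_a and
    part_of descendants of each excluded term. Returns the filtered set and
    the removed-gene list for the run report. Idempotent.
    """
    excluded_terms = list(excluded_terms)
    unknown = [t for t in excluded_terms if t not in dag]
    if unknown:
        raise ValueError(f"excluded term(s) not in the ontology: {unknown}")
    banned: set[str] = set()
    for t in excluded_terms:
        banned |= dag.descendants(t)
    removed = sorted(
        g for g in degs.genes if annot.get(g, set()) & banned
    )
    kept = degs.genes - set(removed)
    return (
        DEGSet(
            genes=kept,
            direction={g: d for g, d in degs.direction.items() if g in kept},
            provenance=degs.provenance,
        ),
        removed,
    )


def overlap_sets(named_sets: Mapping[str, DEGSet | set]) -> pd.DataFrame:
    """All Venn regions of >= 2 named sets, with counts and gene lists.

    Each row is one region of the Venn diagram, identified by the
    pipe-joined names of the sets containing its members; region counts sum
    to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    plain = {
        name: (s.genes if isinstance(s, DEGSet) else set(s))
        for name, s in named_sets.items()
    }
    names = list(plain)
    regions: dict[tuple[bool, ...], set[str]] = {}
    for gene in set().union(*plain.values()):
        pattern = tuple(gene in plain[n] for n in names)
        regions.setdefault(pattern, set()).add(gene)
    rows = []
    for pattern in sorted(regions, reverse=True):
        members = regions[pattern]
        rows.append(
            {
                "region": "|".join(n for n, p in zip(names, pattern) if p),
                "count": len(members),
                "genes": ",".join(sorted(members)),
            }
        )
    return pd.DataFrame(rows, columns=["region", "count", "genes"])
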