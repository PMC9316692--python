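"""Over-representation core: hypergeometric upper tail, BH adjustment, ORA.

One engine serves three uses: GO/pathway ORA on DEG lists, miRNA-target
enrichment (nominating the miRNAs whose known targets are over-represented
among the DEGs), and category ORA over miRNA sets. Significance is the
hypergeometric upper tail P(X >= k) — identical to a one-sided Fisher exact
test on the corresponding 2x2 table — followed by Benjamini-Hochberg
adjustment across tested categories.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import DEGSet, RegulatoryDB

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["category", "k", "K", "n", "N", "pvalue", "padj", "members"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the category size, ``n`` the query size
    and ``k`` the observed overlap. Equals the one-sided Fisher exact p-value
    of the 2x2 table [[k, n-k], [K-k, N-K-n+k]].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1, where (i) indexes
    the ascending sort of the m input p-values.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)]
        raise ValueError(f"p-values outside [0, 1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ora(
    query: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each category against ``universe``.

    Query members outside the universe are dropped (and logged). Categories
    are intersected with the universe; those with zero query overlap or with
    size outside [min_category_size, max_category_size] are skipped before
    BH, so m equals the number of actually tested categories. Rows are sorted
    by ascending p-value; ``significant`` flags padj <= fdr_alpha.
    """
    cfg = cfg or PipelineConfig()
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    dropped = query - universe
    if dropped:
        logger.info("ora: %d query members outside universe dropped", len(dropped))
    query &= universe
    if not query:
        raise ValueError("query has no members inside the universe")

    N, n = len(universe), len(query)
    rows = []
    for name, members in categories.items():
        cat = set(members) & universe
        K = len(cat)
        if K < cfg.min_category_size:
            continue
        if cfg.max_category_size is not None and K > cfg.max_category_size:
            continue
        overlap = cat & query
        k = len(overlap)
        if k == 0:
            logger.debug("ora: category %s has zero overlap, skipped", name)
            continue
        rows.append(
            {
                "category": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": hypergeom_upper(k, K, n, N),
                "members": ",".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS + ["significant"])
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["pvalue"])
    df["significant"] = df["padj"] <= cfg.fdr_alpha
    df = df.sort_values(["pvalue", "category"], kind="stable").reset_index(drop=True)
    return df[ENRICHMENT_COLUMNS + ["significant"]]


def enrich_mirnas(
    degs: DEGSet,
    regdb: RegulatoryDB,
    universe: Iterable[str],
    cfg: PipelineConfig | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Nominate miRNAs whose target genes are enriched in the DEG set.

    Each miRNA's category is its target-gene set (intersected with the
    universe of tested genes); the query is the DEG set. Returns the set of
    miRNAs passing the FDR cutoff together with the full enrichment table.
    Evidence filtering of mirna->gene edges is off by default and applied at
    network construction instead; enable ``cfg.filter_enrichment_evidence``
    to restrict target sets to the required evidence class here too.
    """
    cfg = cfg or PipelineConfig()
    evidence = cfg.evidence_required if cfg.filter_enrichment_evidence else None
    targets = regdb.mirna_targets(evidence=evidence)
    universe = set(universe)
    testable = {
        m: tg & universe for m, tg in targets.items() if tg & universe
    }
    if not testable:
        logger.warning("enrich_mirnas: no miRNA has targets in the universe")
        return set(), pd.DataFrame(columns=ENRICHMENT_COLUMNS + ["significant"])
    table = ora(degs.genes, testable, universe, cfg)
    enriched = set(table.loc[table["significant"], "category"])
    return enriched, table
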