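"""Co-regulatory network assembly, disease contextualization and hotspots.

The network combines transcriptional (tf->gene, tf->mirna) and
post-transcriptional (mirna->gene, mirna->mirna) interactions among the
deregulated entities: an edge enters only if BOTH endpoints are candidates
(DEGs or enriched miRNAs) and the interaction carries the required evidence
label. Contextualization keeps only edges touching a disease-associated
node. Hotspots are the union of the top fraction of nodes under four
centrality measures: degree, betweenness, closeness and eigenvector.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import DEGSet, RegulatoryDB

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = ["degree", "betweenness", "closeness", "eigenvector"]


def build_grn(
    degs: DEGSet,
    mirnas: Iterable[str],
    regdb: RegulatoryDB,
    cfg: PipelineConfig | None = None,
) -> nx.MultiDiGraph:
    """Assemble the co-regulatory network over DEGs and enriched miRNAs.

    Candidate nodes are ``degs`` union ``mirnas``; an interaction is kept iff
    both endpoints are candidates and its evidence equals
    ``cfg.evidence_required``. The same node pair may carry several typed
    edges (e.g. tf->gene and mirna->gene under different identifiers), kept
    as distinct edges. Isolated candidates are left out of the graph but
    recorded under ``graph.graph["isolated_candidates"]``. An empty result
    is a warning, not an error.
    """
    cfg = cfg or PipelineConfig()
    mirnas = set(mirnas)
    candidates = set(degs.genes) | mirnas
    if not candidates:
        raise ValueError("no candidate nodes: DEG set and miRNA set both empty")
    kinds = regdb.node_kinds()

    g = nx.MultiDiGraph()
    df = regdb.interactions
    keep = (
        df["source"].isin(candidates)
        & df["target"].isin(candidates)
        & (df["evidence"] == cfg.evidence_required)
    )
    for row in df[keep].itertuples(index=False):
        g.add_edge(
            row.source,
            row.target,
            interaction=f"{row.source_type}-{row.target_type}",
            evidence=row.evidence,
        )
    for node in g.nodes:
        g.nodes[node]["kind"] = "mirna" if node in mirnas else kinds.get(node, "gene")
        g.nodes[node]["is_deg"] = node in degs.genes
        g.nodes[node]["is_enriched_mirna"] = node in mirnas
    g.graph["isolated_candidates"] = sorted(candidates - set(g.nodes))
    if g.number_of_edges() == 0:
        logger.warning("build_grn: no interaction survived the filters; empty GRN")
    return g


def contextualize_disease(grn: nx.MultiDiGraph, assoc: Iterable[str]) -> nx.MultiDiGraph:
    """Keep only edges with a disease-associated source or target.

    Nodes left isolated by the edge filter are dropped; remaining nodes get
    an ``is_disease`` attribute. Idempotent, and a no-op when every node is
    associated.
    """
    assoc = set(assoc)
    out = nx.MultiDiGraph(**grn.graph)
    for u, v, key, d in grn.edges(keys=True, data=True):
        if u in assoc or v in assoc:
            out.add_edge(u, v, key=key, **d)
    for node in out.nodes:
        out.nodes[node].update(grn.nodes[node])
        out.nodes[node]["is_disease"] = node in assoc
    return out


def _power_iteration_eigenvector(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Principal eigenvector of a symmetric non-negative adjacency matrix."""
    n = adj.shape[0]
    # A + I shift: same principal eigenvector, but the dominant eigenvalue is
    # strictly largest in magnitude, so bipartite components cannot oscillate
    shifted = adj + np.eye(n)
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(n)
        y /= norm
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    raise RuntimeError(
        "eigenvector centrality power iteration did not converge within "
        f"{max_iter} steps (undirected fallback already applied)"
    )


def centralities(grn: nx.MultiDiGraph) -> pd.DataFrame:
    """Four centrality measures per node.

    degree: total (in + out) degree counting each typed edge once;
    betweenness: shortest-path betweenness on the directed simple graph
    (unnormalized pair counts); closeness: harmonic closeness on the
    undirected skeleton (well-defined under disconnection); eigenvector:
    principal eigenvector of the undirected skeleton's adjacency, by power
    iteration at tolerance 1e-10.
    """
    if grn.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(grn.nodes)
    directed = nx.DiGraph(grn)
    undirected = nx.Graph(directed.to_undirected())

    degree = dict(grn.degree())
    betweenness = nx.betweenness_centrality(directed, normalized=False)
    closeness = nx.harmonic_centrality(undirected)
    adj = nx.to_numpy_array(undirected, nodelist=nodes, weight=None)
    eig = _power_iteration_eigenvector(adj)
    eig = np.abs(eig)

    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "eigenvector": eig,
        },
        index=pd.Index(nodes, name="node"),
    )


def _top_fraction(scores: pd.Series, fraction: float) -> set[str]:
    """Nodes with score >= the score at rank ceil(fraction * n), ties included."""
    n = len(scores)
    cutoff_rank = max(1, math.ceil(fraction * n))
    ordered = scores.sort_values(ascending=False, kind="stable")
    threshold = ordered.iloc[cutoff_rank - 1]
    return set(scores.index[scores >= threshold])


def hotspots(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    kinds: Mapping[str, str] | None = None,
) -> set[str]:
    """Hotspot nodes: union of top-fraction selections over the four measures.

    Per measure, the cutoff rank is ceil(hotspot_fraction * n) and every node
    tied with the cutoff score is included. With ``cfg.hotspots_per_kind``
    and a node->kind map, the rule is applied separately to genes and miRNAs
    and the selections unioned.
    """
    cfg = cfg or PipelineConfig()
    if table.empty:
        raise ValueError("empty centrality table")
    selected: set[str] = set()
    if cfg.hotspots_per_kind and kinds:
        groups = {}
        for node in table.index:
            groups.setdefault(kinds.get(node, "gene"), []).append(node)
        partitions = [table.loc[members] for members in groups.values()]
    else:
        partitions = [table]
    for part in partitions:
        for measure in CENTRALITY_MEASURES:
            selected |= _top_fraction(part[measure], cfg.hotspot_fraction)
    return selected


def flag_hotspots(grn: nx.MultiDiGraph, hotspot_nodes: Iterable[str]) -> None:
    """Set the is_hotspot node attribute in place."""
    hs = set(hotspot_nodes)
    for node in grn.nodes:
        grn.nodes[node]["is_hotspot"] = node in hs
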