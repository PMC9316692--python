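"""Gene Ontology DAG container and annotation map.

The DAG is held as a directed graph with child -> parent edges labelled by
relation (``is_a`` or ``part_of``). Each namespace has exactly one root and
every term must reach it, which is what both annotation propagation (for
functional-term exclusion) and Wang-style similarity require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

VALID_RELATIONS = {"is_a", "part_of"}


@dataclass
class GoDag:
    """Rooted ontology DAG; ``graph`` edges point child -> parent."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        g = self.graph
        for u, v, d in g.edges(data=True):
            rel = d.get("relation")
            if rel not in VALID_RELATIONS:
                raise ValueError(f"edge {u}->{v} has unknown relation {rel!r}")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"DAG violation: cycle {cycle}")
        for ns, root in self.roots.items():
            members = [t for t in g if g.nodes[t].get("namespace", "GO") == ns]
            for t in members:
                if t != root and not nx.has_path(g, t, root):
                    raise ValueError(f"term {t} cannot reach root {root} of {ns}")

    @property
    def roots(self) -> dict[str, str]:
        """namespace -> root term (unique out-degree-0 term per namespace)."""
        by_ns: dict[str, list[str]] = {}
        for t in self.graph:
            if self.graph.out_degree(t) == 0:
                ns = self.graph.nodes[t].get("namespace", "GO")
                by_ns.setdefault(ns, []).append(t)
        for ns, roots in by_ns.items():
            if len(roots) != 1:
                raise ValueError(f"namespace {ns} has {len(roots)} roots: {roots}")
        return {ns: roots[0] for ns, roots in by_ns.items()}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "GO")

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return list(self.graph)
        return [t for t in self.graph if self.namespace(t) == namespace]

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs for direct parents of ``term``."""
        return [(p, self.graph.edges[term, p]["relation"]) for p in self.graph.successors(term)]

    def children(self, term: str) -> list[tuple[str, str]]:
        return [(c, self.graph.edges[c, term]["relation"]) for c in self.graph.predecessors(term)]

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including itself (is_a and part_of)."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term}")
        return {term} | nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All descendants of ``term`` including itself."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term}")
        return {term} | nx.ancestors(self.graph, term)


AnnotationMap = dict[str, set[str]]


def validate_annotations(annot: Mapping[str, Iterable[str]], dag: GoDag) -> AnnotationMap:
    """Normalize gene->terms mapping, rejecting annotations to unknown terms."""
    out: AnnotationMap = {}
    for gene, terms in annot.items():
        terms = set(terms)
        unknown = {t for t in terms if t not in dag}
        if unknown:
            raise ValueError(f"gene {gene} annotated to unknown terms: {sorted(unknown)}")
        if terms:
            out[str(gene)] = terms
    return out


def annotated_genes(annot: AnnotationMap, dag: GoDag, namespace: str | None = None) -> set[str]:
    """Genes with >= 1 annotation, optionally restricted to one namespace."""
    if namespace is None:
        return {g for g, ts in annot.items() if ts}
    return {
        g for g, ts in annot.items() if any(dag.namespace(t) == namespace for t in ts)
    }
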