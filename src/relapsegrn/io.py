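"""Readers and writers for all on-disk formats.

Everything is plain TSV (UTF-8, ``#`` comment lines, no quoting) except gene
sets (GMT) and networks (SIF-style edge lists). GO input is accepted either
as a two-file TSV (edges + annotations) or as a minimal OBO subset; both are
normalized to the same in-memory :class:`~relapsegrn.ontology.GoDag`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .containers import (
    REGDB_COLUMNS,
    CountMatrix,
    DEGSet,
    DiseaseAssociations,
    RegulatoryDB,
)
from .ontology import AnnotationMap, GoDag, validate_annotations


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    return df


def read_count_matrix(path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV plus a (sample, group) companion table.

    Cells must be non-negative integers; a fractional or negative cell is
    reported with its gene and sample ID.
    """
    raw = _read_tsv(path)
    if raw.empty:
        raise ValueError(f"{path}: no data rows")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ID(s) {dups}")
    body = raw.drop(columns=[gene_col])
    parsed = {}
    for sample in body.columns:
        col = pd.to_numeric(body[sample], errors="coerce")
        bad = col.isna() | (col % 1 != 0) | (col < 0)
        if bad.any():
            g = genes[bad].iloc[0]
            v = body.loc[bad, sample].iloc[0]
            raise ValueError(
                f"{path}: cell value {v!r} for gene {g}, sample {sample} "
                "is not a non-negative integer"
            )
        parsed[sample] = col.astype("int64")
    counts = pd.DataFrame(parsed)
    counts.index = pd.Index(genes, name=gene_col)
    gdf = _read_tsv(groups_path)
    if gdf.shape[1] < 2:
        raise ValueError(f"{groups_path}: expected columns (sample, group)")
    groups = pd.Series(
        gdf.iloc[:, 1].to_numpy(), index=pd.Index(gdf.iloc[:, 0]), name="group"
    )
    return CountMatrix(counts=counts, groups=groups)


def write_count_matrix(cm: CountMatrix, path: str | Path, groups_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")
    pd.DataFrame({"sample": cm.sample_ids, "group": cm.groups.to_numpy()}).to_csv(
        groups_path, sep="\t", index=False
    )


def read_regdb(path: str | Path) -> RegulatoryDB:
    """Read a (source, target, source_type, target_type, evidence) table."""
    df = _read_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if list(df.columns[:5]) != REGDB_COLUMNS:
        # headerless dialect: exactly five columns in canonical order
        if df.shape[1] == 5:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)
            df.columns = REGDB_COLUMNS
        else:
            raise ValueError(
                f"{path}: expected columns {REGDB_COLUMNS}, got {list(df.columns)}"
            )
    return RegulatoryDB(interactions=df)


def write_regdb(db: RegulatoryDB, path: str | Path) -> None:
    db.interactions.to_csv(path, sep="\t", index=False)


def read_disease(path: str | Path) -> DiseaseAssociations:
    df = _read_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return DiseaseAssociations(entities=df)


def write_disease(assoc: DiseaseAssociations, path: str | Path) -> None:
    assoc.entities.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets in GMT dialect: name<TAB>description<TAB>members..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, members")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = {p for p in parts[2:] if p}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_go(
    path_edges: str | Path, path_annot: str | Path
) -> tuple[GoDag, AnnotationMap]:
    """Read a GO DAG plus annotations.

    ``path_edges`` is either a TSV (child, parent, relation[, namespace]) or a
    minimal OBO file (detected by the ``format-version:``/``[Term]`` header);
    ``path_annot`` is a (gene, term) TSV. Annotations to unknown terms and
    cyclic is_a edges are rejected.
    """
    edges_path = Path(path_edges)
    with open(edges_path, encoding="utf-8") as fh:
        head = fh.read(2048)
    if "[Term]" in head or head.startswith("format-version"):
        dag = _go_from_obo(edges_path)
    else:
        dag = _go_from_edges_tsv(edges_path)
    adf = _read_tsv(path_annot)
    if adf.shape[1] < 2:
        raise ValueError(f"{path_annot}: expected columns (gene, term)")
    annot: dict[str, set[str]] = {}
    for gene, term in zip(adf.iloc[:, 0], adf.iloc[:, 1]):
        annot.setdefault(gene, set()).add(term)
    return dag, validate_annotations(annot, dag)


def _go_from_edges_tsv(path: Path) -> GoDag:
    df = _read_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError(f"{path}: expected columns (child, parent, relation)")
    g = nx.DiGraph()
    has_ns = len(cols) >= 4
    for _, row in df.iterrows():
        child, parent, rel = row.iloc[0], row.iloc[1], row.iloc[2]
        g.add_edge(child, parent, relation=rel)
        if has_ns and isinstance(row.iloc[3], str):
            g.nodes[child]["namespace"] = row.iloc[3]
            g.nodes[parent].setdefault("namespace", row.iloc[3])
    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise ValueError(f"{path}: DAG violation, cycle through {cycle}")
    return GoDag(graph=g)


def _go_from_obo(path: Path) -> GoDag:
    net = obonet.read_obo(path)
    g = nx.DiGraph()
    for child, parent, key in net.edges(keys=True):
        rel = "is_a" if key == "is_a" else key
        if rel in ("is_a", "part_of"):
            g.add_edge(child, parent, relation=rel)
    for term, data in net.nodes(data=True):
        if term in g and "namespace" in data:
            g.nodes[term]["namespace"] = data["namespace"]
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"{path}: DAG violation")
    return GoDag(graph=g)


def write_go(dag: GoDag, annot: AnnotationMap, path_edges: str | Path, path_annot: str | Path) -> None:
    rows = [
        {
            "child": u,
            "parent": v,
            "relation": d["relation"],
            "namespace": dag.namespace(u),
        }
        for u, v, d in dag.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["child", "parent", "relation", "namespace"]).to_csv(
        path_edges, sep="\t", index=False
    )
    arows = [
        {"gene": g, "term": t} for g in sorted(annot) for t in sorted(annot[g])
    ]
    pd.DataFrame(arows, columns=["gene", "term"]).to_csv(path_annot, sep="\t", index=False)


def read_de_results(path: str | Path) -> pd.DataFrame:
    """Import externally produced DE results (gene, baseMeanA, baseMeanB, log2FC, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = ["gene", "baseMeanA", "baseMeanB", "log2FC", "pvalue", "padj"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE results missing columns {missing}")
    return df.set_index("gene")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV."""
    df.to_csv(path, sep="\t", index=index)


def write_network(grn: nx.MultiDiGraph, path: str | Path) -> None:
    """Write a GRN as a SIF-style edge list: source, interaction class, target."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, d in sorted(grn.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("interaction", ""))):
            fh.write(f"{u}\t{d.get('interaction', 'regulates')}\t{v}\n")


def read_network_nodes(path: str | Path) -> set[str]:
    """Node set of a SIF file (for downstream semantic validation)."""
    nodes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:
                nodes.add(parts[0])
                nodes.add(parts[2])
    return nodes


def write_degset(degs: DEGSet, path: str | Path) -> None:
    rows = [
        {"gene": g, "direction": "up" if degs.direction.get(g, 1) > 0 else "down"}
        for g in sorted(degs.genes)
    ]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(path, sep="\t", index=False)


def read_degset(path: str | Path, provenance: tuple[str, ...] = ()) -> DEGSet:
    df = _read_tsv(path)
    if df.empty:
        return DEGSet(genes=set(), provenance=provenance)
    genes = set(df["gene"])
    direction = {
        g: (1 if d == "up" else -1) for g, d in zip(df["gene"], df["direction"])
    }
    return DEGSet(genes=genes, direction=direction, provenance=provenance)
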