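"""Seeded synthetic-data generators with planted ground truth.

These generators emulate the statistical structure of a two-group RNA-seq
relapse experiment and its public-knowledge context: negative-binomial counts
with a planted fraction of differentially expressed genes, a regulatory
database in which some miRNAs preferentially target those genes, a disease
association list, and a GO DAG in which a planted gene module is annotated to
neighbouring terms (functionally homogeneous by construction).

Every generator is a pure function of its arguments including the seed; one
master seed feeds independent per-generator streams so that stages remain
reproducible when re-run alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountMatrix, RegulatoryDB
from .ontology import AnnotationMap, GoDag

# sub-stream identifiers so generators sharing one master seed stay independent
_STREAM = {"counts": 1, "regdb": 2, "go": 3, "disease": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    seed: int
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true log2FC
    enriched_mirnas: set[str] = field(default_factory=set)
    homogeneous_module: set[str] = field(default_factory=set)
    disease_entities: set[str] = field(default_factory=set)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            seed=self.seed,
            de_genes={**self.de_genes, **other.de_genes},
            enriched_mirnas=self.enriched_mirnas | other.enriched_mirnas,
            homogeneous_module=self.homogeneous_module | other.homogeneous_module,
            disease_entities=self.disease_entities | other.disease_entities,
        )


def gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + dispersion * mu^2) samples, elementwise over mu."""
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    n_genes: int,
    n_per_group: int,
    de_fraction: float,
    lfc_mean: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a two-group NB count matrix with planted DE genes.

    Baseline means are log-normal (log-mean log 100, log-sd 1); counts are
    negative binomial with variance ``mu + dispersion * mu^2``. A
    ``de_fraction`` subset of genes has its group-B mean multiplied by
    ``2 ** (+/- lfc_mean)`` with random sign; the truth records the planted
    genes and their signed log2 fold changes.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= de_fraction < 1:
        raise ValueError("de_fraction must be in [0, 1)")
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    rng = _rng(seed, "counts")
    genes = gene_names(n_genes)
    base_mu = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = signs * lfc_mean

    mu_a = np.repeat(base_mu[:, None], n_per_group, axis=1)
    mu_b = np.repeat((base_mu * 2.0**lfc)[:, None], n_per_group, axis=1)
    counts_a = _nb_draw(rng, mu_a, dispersion)
    counts_b = _nb_draw(rng, mu_b, dispersion)

    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    counts = pd.DataFrame(
        np.hstack([counts_a, counts_b]).astype("int64"),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    groups = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group"
    )
    truth = SyntheticTruth(
        seed=seed, de_genes={genes[i]: float(lfc[i]) for i in de_idx}
    )
    return CountMatrix(counts=counts, groups=groups), truth


def simulate_regdb(
    n_tfs: int,
    n_mirnas: int,
    n_genes: int,
    targets_per_regulator: int = 20,
    n_planted: int = 1,
    planted_fraction: float = 0.8,
    evidence_mix: float = 0.7,
    de_genes: set[str] | None = None,
    seed: int = 0,
) -> tuple[RegulatoryDB, SyntheticTruth]:
    """Simulate a typed regulatory-interaction database.

    Background regulators target uniform-random genes; the first ``n_planted``
    miRNAs instead draw ``planted_fraction`` of their targets from
    ``de_genes`` (the planted enrichment signal). All four edge classes
    (tf->gene, tf->mirna, mirna->gene, mirna->mirna) are represented and each
    edge carries evidence "experimental" with probability ``evidence_mix``,
    else "predicted".
    """
    if min(n_tfs, n_mirnas, n_genes, targets_per_regulator) <= 0:
        raise ValueError("counts must be positive")
    if not 0 <= planted_fraction <= 1 or not 0 <= evidence_mix <= 1:
        raise ValueError("proportions must be in [0, 1]")
    if n_planted > n_mirnas:
        raise ValueError(f"n_planted={n_planted} exceeds n_mirnas={n_mirnas}")
    if n_tfs >= n_genes:
        raise ValueError("n_tfs must be smaller than n_genes")
    rng = _rng(seed, "regdb")
    genes = np.array(gene_names(n_genes))
    mirnas = [f"mir-{i}" for i in range(n_mirnas)]
    # TFs are themselves genes of the universe (regulators with gene IDs)
    tfs = [str(t) for t in rng.choice(genes, size=n_tfs, replace=False)]
    de_pool = np.array(sorted(de_genes)) if de_genes else np.array([], dtype=object)
    bg_pool = (
        np.array(sorted(set(genes) - set(de_pool))) if len(de_pool) else genes
    )

    rows: list[tuple[str, str, str, str]] = []
    planted = set(mirnas[:n_planted]) if len(de_pool) else set()
    for m in mirnas:
        if m in planted:
            n_de = int(round(planted_fraction * targets_per_regulator))
            n_de = min(n_de, len(de_pool))
            tg = list(rng.choice(de_pool, size=n_de, replace=False))
            n_bg = targets_per_regulator - n_de
            tg += list(rng.choice(bg_pool, size=min(n_bg, len(bg_pool)), replace=False))
        else:
            tg = list(rng.choice(genes, size=min(targets_per_regulator, len(genes)), replace=False))
        rows += [(m, t, "mirna", "gene") for t in tg]
    for tf in tfs:
        pool = genes[genes != tf]  # no self-regulation
        tg = rng.choice(pool, size=min(targets_per_regulator, len(pool)), replace=False)
        rows += [(tf, t, "tf", "gene") for t in tg]
        # every TF also regulates one miRNA; a sprinkling of mirna->mirna edges
        rows.append((tf, str(rng.choice(mirnas)), "tf", "mirna"))
    for m in mirnas[: max(1, n_mirnas // 5)]:
        other = str(rng.choice([x for x in mirnas if x != m]))
        rows.append((m, other, "mirna", "mirna"))

    evidence = np.where(
        rng.random(len(rows)) < evidence_mix, "experimental", "predicted"
    )
    df = pd.DataFrame(rows, columns=["source", "target", "source_type", "target_type"])
    df["evidence"] = evidence
    truth = SyntheticTruth(seed=seed, enriched_mirnas=planted)
    return RegulatoryDB(interactions=df), truth


def simulate_go(
    n_genes: int,
    module_size: int,
    seed: int = 0,
    branching: int = 3,
    depth: int = 4,
    part_of_fraction: float = 0.1,
    annotations_per_gene: int = 2,
    namespace: str = "biological_process",
    modules: list[set[str]] | None = None,
) -> tuple[GoDag, AnnotationMap, SyntheticTruth]:
    """Simulate a rooted GO-like DAG with a planted homogeneous gene module.

    The DAG is a complete ``branching``-ary tree of the given ``depth`` with
    is_a edges plus a fraction of part_of shortcut edges toward shallower
    terms (still acyclic). Background genes are annotated to uniform-random
    leaves; the planted module's genes are annotated to leaves below one
    common depth-1 ancestor, so their pairwise Wang similarity exceeds the
    background by construction. Passing ``modules`` plants several gene
    modules instead (one depth-1 anchor each, cycling); the study preset
    uses this to make each contrast's network genes cohesive.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if module_size > n_genes:
        raise ValueError("module_size cannot exceed n_genes")
    rng = _rng(seed, "go")

    g = nx.DiGraph()
    counter = 0

    def new_term() -> str:
        nonlocal counter
        t = f"GO:{counter:07d}"
        counter += 1
        return t

    root = new_term()
    g.add_node(root, namespace=namespace, depth=0)
    levels: list[list[str]] = [[root]]
    for d in range(1, depth + 1):
        level = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                t = new_term()
                g.add_node(t, namespace=namespace, depth=d)
                g.add_edge(t, parent, relation="is_a")
                level.append(t)
        levels.append(level)
    # part_of shortcuts: deep term -> strictly shallower non-parent term
    deep = [t for d in range(2, depth + 1) for t in levels[d]]
    n_short = int(round(part_of_fraction * len(deep)))
    for t in rng.choice(deep, size=n_short, replace=False):
        t_depth = g.nodes[t]["depth"]
        target_level = int(rng.integers(0, t_depth - 1 + 1))
        cand = [x for x in levels[target_level] if not g.has_edge(t, x)]
        if cand:
            g.add_edge(t, str(rng.choice(cand)), relation="part_of")

    leaves = levels[depth]
    genes = gene_names(n_genes)
    dag = GoDag(graph=g)
    if modules is None:
        modules = (
            [set(rng.choice(genes, size=module_size, replace=False))]
            if module_size
            else []
        )
    # each module's annotation pool: leaves under one depth-1 anchor
    anchors = list(rng.permutation(levels[1]))
    pool_of: dict[str, list[str]] = {}
    for i, module in enumerate(modules):
        anchor = anchors[i % len(anchors)]
        module_leaves = sorted(set(leaves) & dag.descendants(anchor))
        for gene in module:
            pool_of.setdefault(gene, module_leaves)

    annot: AnnotationMap = {}
    for gene in genes:
        k = int(rng.integers(1, annotations_per_gene + 1))
        pool = pool_of.get(gene, leaves)
        terms = rng.choice(pool, size=min(k, len(pool)), replace=False)
        annot[gene] = {str(t) for t in terms}
    truth = SyntheticTruth(
        seed=seed, homogeneous_module=set().union(*modules) if modules else set()
    )
    return dag, annot, truth


def plant_mirna_targets(
    regdb: RegulatoryDB,
    mirna: str,
    de_genes: set[str],
    all_genes: list[str],
    targets_per_regulator: int = 20,
    planted_fraction: float = 0.8,
    evidence: str = "experimental",
    seed: int = 0,
) -> RegulatoryDB:
    """Add one miRNA whose targets are drawn mostly from ``de_genes``.

    Used by the study-level preset to plant one enriched miRNA per contrast
    into a shared background database. The planted edges carry the given
    evidence label so they survive the network evidence filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    de_pool = np.array(sorted(de_genes))
    bg_pool = np.array(sorted(set(all_genes) - set(de_genes)))
    n_de = min(int(round(planted_fraction * targets_per_regulator)), len(de_pool))
    tg = list(rng.choice(de_pool, size=n_de, replace=False))
    n_bg = min(targets_per_regulator - n_de, len(bg_pool))
    tg += list(rng.choice(bg_pool, size=n_bg, replace=False))
    rows = pd.DataFrame(
        {
            "source": mirna,
            "target": tg,
            "source_type": "mirna",
            "target_type": "gene",
            "evidence": evidence,
        }
    )
    merged = pd.concat([regdb.interactions, rows], ignore_index=True)
    return RegulatoryDB(interactions=merged)


def plant_tf_hub(
    regdb: RegulatoryDB,
    hub_gene: str,
    de_genes: set[str],
    hub_fraction: float = 0.3,
    evidence: str = "experimental",
    seed: int = 0,
) -> RegulatoryDB:
    """Wire one DE gene as a master-regulator TF of its DE module.

    The hub gains experimental tf->gene edges to ``hub_fraction`` of the
    other DE genes, emulating a driver transcription factor whose centrality
    should place it among the hotspots.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    pool = np.array(sorted(de_genes - {hub_gene}))
    n = int(round(hub_fraction * len(pool)))
    tg = rng.choice(pool, size=n, replace=False)
    rows = pd.DataFrame(
        {
            "source": hub_gene,
            "target": tg,
            "source_type": "tf",
            "target_type": "gene",
            "evidence": evidence,
        }
    )
    merged = pd.concat([regdb.interactions, rows], ignore_index=True)
    return RegulatoryDB(interactions=merged)


def simulate_disease(
    entities: list[str] | set[str],
    flag_fraction: float,
    must_include: set[str] | None = None,
    seed: int = 0,
) -> set[str]:
    """Flag a random subset of entities as disease-associated.

    Each entity is flagged independently with probability ``flag_fraction``;
    every ``must_include`` entity is flagged regardless of the draw.
    """
    if not 0 <= flag_fraction <= 1:
        raise ValueError("flag_fraction must be in [0, 1]")
    rng = _rng(seed, "disease")
    ordered = sorted(entities)
    draw = rng.random(len(ordered)) < flag_fraction
    flagged = {e for e, f in zip(ordered, draw) if f}
    return flagged | set(must_include or ())


@dataclass
class StudyData:
    """A full synthetic study: per-contrast counts plus shared context."""

    contrasts: dict[str, CountMatrix]
    regdb: RegulatoryDB
    disease: set[str]
    dag: GoDag
    annot: AnnotationMap
    truth: SyntheticTruth
    per_contrast_truth: dict[str, SyntheticTruth]
    planted_mirna: dict[str, str]  # contrast -> its planted miRNA
    planted_hub: dict[str, str] = field(default_factory=dict)  # contrast -> hub TF gene


def _child_seed(seed: int, *key: int) -> int:
    """Derive a reproducible sub-seed below 2**31 from the master seed."""
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % 2**31)


def simulate_study(
    seed: int,
    contrast_names: list[str] | None = None,
    n_genes: int = 2000,
    n_per_group: int = 5,
    de_fraction: float = 0.1,
    lfc_mean: float = 2.0,
    dispersion: float = 0.1,
    n_tfs: int = 80,
    n_mirnas: int = 40,
    targets_per_regulator: int = 25,
    planted_fraction: float = 0.8,
    evidence_mix: float = 0.7,
    disease_fraction: float = 0.4,
    go_branching: int = 3,
    go_depth: int = 4,
) -> StudyData:
    """Generate the default multi-contrast synthetic study.

    Mirrors the design of a two-cell-line, two-drug relapse experiment: each
    contrast gets its own NB count matrix with planted DE genes; a shared
    regulatory database carries one planted miRNA per contrast that
    preferentially (``planted_fraction``) targets that contrast's DE genes
    with experimental evidence; a shared disease list includes every planted
    miRNA; and the GO DAG annotates each contrast's DE genes under a common
    ancestor so its network genes are functionally homogeneous.
    """
    if contrast_names is None:
        contrast_names = ["lineA-drugX", "lineA-drugY"]
    contrasts: dict[str, CountMatrix] = {}
    per_truth: dict[str, SyntheticTruth] = {}
    for i, name in enumerate(contrast_names):
        cm, t = simulate_counts(
            n_genes,
            n_per_group,
            de_fraction,
            lfc_mean,
            dispersion,
            seed=_child_seed(seed, 10, i),
        )
        contrasts[name] = cm
        per_truth[name] = t

    regdb, _ = simulate_regdb(
        n_tfs,
        n_mirnas,
        n_genes,
        targets_per_regulator,
        n_planted=0,
        evidence_mix=evidence_mix,
        seed=_child_seed(seed, 11),
    )
    genes = gene_names(n_genes)
    planted_mirna: dict[str, str] = {}
    for i, name in enumerate(contrast_names):
        mirna = f"mir-planted-{i}"
        regdb = plant_mirna_targets(
            regdb,
            mirna,
            set(per_truth[name].de_genes),
            genes,
            targets_per_regulator,
            planted_fraction,
            seed=_child_seed(seed, 12, i),
        )
        planted_mirna[name] = mirna
        per_truth[name].enriched_mirnas.add(mirna)

    planted_hub: dict[str, str] = {}
    for i, name in enumerate(contrast_names):
        de = per_truth[name].de_genes
        hub_rng = np.random.default_rng(
            np.random.SeedSequence([_child_seed(seed, 15, i), 8])
        )
        # the hub is a clearly deregulated, well-expressed driver: draw it
        # from DE genes in the upper half by mean count whose realized
        # group-mean log2 ratio also reflects the planted effect
        cm = contrasts[name]
        lev_a, lev_b = cm.group_levels
        mean_a = cm.counts[cm.samples_of(lev_a)].mean(axis=1)
        mean_b = cm.counts[cm.samples_of(lev_b)].mean(axis=1)
        realized_lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
        mean_count = cm.counts.mean(axis=1)
        pool = sorted(
            g
            for g in de
            if mean_count[g] >= mean_count[sorted(de)].median()
            and abs(realized_lfc[g]) >= 0.9 * abs(de[g])
        )
        hub = str(hub_rng.choice(pool))
        regdb = plant_tf_hub(
            regdb, hub, set(de), seed=_child_seed(seed, 16, i)
        )
        planted_hub[name] = hub

    dag, annot, go_truth = simulate_go(
        n_genes,
        module_size=0,
        seed=_child_seed(seed, 13),
        branching=go_branching,
        depth=go_depth,
        modules=[set(per_truth[n].de_genes) for n in contrast_names],
    )
    entities = (
        set(genes)
        | {f"mir-{i}" for i in range(n_mirnas)}
        | set(planted_mirna.values())
    )
    disease = simulate_disease(
        entities,
        disease_fraction,
        must_include=set(planted_mirna.values()) | set(planted_hub.values()),
        seed=_child_seed(seed, 14),
    )

    truth = SyntheticTruth(seed=seed)
    for t in per_truth.values():
        truth = truth.merge(t)
    truth.homogeneous_module = go_truth.homogeneous_module
    truth.disease_entities = disease
    return StudyData(
        contrasts=contrasts,
        regdb=regdb,
        disease=disease,
        dag=dag,
        annot=annot,
        truth=truth,
        per_contrast_truth=per_truth,
        planted_mirna=planted_mirna,
        planted_hub=planted_hub,
    )
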