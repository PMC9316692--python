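"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

VALID_SOURCE_TYPES = {"tf", "mirna", "gene"}
VALID_TARGET_TYPES = {"gene", "mirna"}


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a two-level group factor.

    ``counts`` rows are genes, columns samples; ``groups`` maps every sample
    to its condition label. Exactly two levels with at least two samples each
    are required, matching a two-group differential-expression contrast with
    biological replicates.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("count matrix must be integer-valued")
        if (vals < 0).any():
            raise ValueError("count matrix contains negative values")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.counts.columns[self.groups.isna()].tolist()
            raise ValueError(f"samples without group label: {missing}")
        levels = self.groups.unique()
        if len(levels) != 2:
            raise ValueError(f"expected exactly two groups, got {list(levels)}")
        sizes = self.groups.value_counts()
        if (sizes < 2).any():
            raise ValueError(f"each group needs >= 2 samples, got {sizes.to_dict()}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_levels(self) -> tuple[str, str]:
        """The two group labels in order of first appearance (A, B)."""
        seen = list(dict.fromkeys(self.groups))
        return seen[0], seen[1]

    def samples_of(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])


@dataclass
class DEGSet:
    """A called set of differentially expressed genes with directions.

    ``direction`` maps each member to +1 (up in group B) or -1 (down).
    ``provenance`` carries free-form contrast labels, e.g.
    ``("RS4;11", "Dexa", "144h_vs_control")``.
    """

    genes: set[str]
    direction: dict[str, int] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        unknown = set(self.direction) - self.genes
        if unknown:
            raise ValueError(f"direction given for non-member genes: {sorted(unknown)}")
        bad = {g: d for g, d in self.direction.items() if d not in (-1, 1)}
        if bad:
            raise ValueError(f"direction must be +1/-1: {bad}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


REGDB_COLUMNS = ["source", "target", "source_type", "target_type", "evidence"]


@dataclass
class RegulatoryDB:
    """Typed, evidence-labelled directed regulatory interactions.

    Rows are (source, target, source_type, target_type, evidence) with
    source_type in {tf, mirna, gene} and target_type in {gene, mirna}.
    Duplicate (source, target, types) rows are collapsed on construction;
    the same node pair may still appear under distinct type combinations
    (distinct typed edges).
    """

    interactions: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.interactions
        missing = [c for c in REGDB_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"regulatory table missing columns: {missing}")
        df = df[REGDB_COLUMNS].astype(str)
        bad_src = set(df["source_type"]) - VALID_SOURCE_TYPES
        if bad_src:
            raise ValueError(f"unknown source_type values: {sorted(bad_src)}")
        bad_tgt = set(df["target_type"]) - VALID_TARGET_TYPES
        if bad_tgt:
            raise ValueError(f"unknown target_type values: {sorted(bad_tgt)}")
        self_loops = df[df["source"] == df["target"]]
        if len(self_loops):
            raise ValueError(
                f"self-loop interactions not allowed: {self_loops['source'].tolist()}"
            )
        df = df.drop_duplicates(
            subset=["source", "target", "source_type", "target_type"]
        ).reset_index(drop=True)
        self.interactions = df

    def __len__(self) -> int:
        return len(self.interactions)

    def mirna_targets(self, evidence: str | None = None) -> dict[str, set[str]]:
        """miRNA -> set of target genes, optionally evidence-filtered."""
        df = self.interactions
        mask = (df["source_type"] == "mirna") & (df["target_type"] == "gene")
        if evidence is not None:
            mask &= df["evidence"] == evidence
        sub = df[mask]
        out: dict[str, set[str]] = {}
        for src, tgt in zip(sub["source"], sub["target"]):
            out.setdefault(src, set()).add(tgt)
        return out

    def node_kinds(self) -> dict[str, str]:
        """Best-effort node kind map: 'mirna' wherever typed so, else 'gene'."""
        kinds: dict[str, str] = {}
        df = self.interactions
        for col, tcol in (("source", "source_type"), ("target", "target_type")):
            for node, typ in zip(df[col], df[tcol]):
                if typ == "mirna":
                    kinds[node] = "mirna"
                else:
                    kinds.setdefault(node, "gene")
        return kinds


@dataclass
class DiseaseAssociations:
    """Entities (genes/miRNAs) associated with a disease label."""

    entities: pd.DataFrame  # columns: entity, entity_type, disease

    def __post_init__(self) -> None:
        need = ["entity", "entity_type", "disease"]
        missing = [c for c in need if c not in self.entities.columns]
        if missing:
            raise ValueError(f"disease table missing columns: {missing}")
        self.entities = self.entities[need].astype(str).drop_duplicates().reset_index(drop=True)

    def for_disease(self, disease: str) -> set[str]:
        df = self.entities
        return set(df.loc[df["disease"] == disease, "entity"])
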