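"""Run configuration for the relapse-GRN pipeline.

All defaults mirror the fixed analysis parameters of the study design this
package implements: DEGs are called at FDR 5% with |log2FC| >= 1.5, network
edges must carry experimental evidence, hotspots are the top 10% of nodes per
centrality measure, and functional homogeneity is judged against 100 random
gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml


@dataclass
class PipelineConfig:
    """Parameters shared across pipeline stages.

    Parameters
    ----------
    fdr_alpha:
        Benjamini-Hochberg adjusted-p cutoff used everywhere an FDR is
        controlled (DEG calling, miRNA enrichment, homogeneity tests).
    lfc_threshold:
        Absolute log2 fold-change cutoff for DEG calling (log2 units).
    hotspot_fraction:
        Fraction of top-ranked nodes kept per centrality measure.
    n_random_sets:
        Number of random gene sets drawn for the homogeneity null.
    evidence_required:
        Evidence label an interaction must carry to enter the GRN.
    disease_context:
        Disease label used when contextualizing the network.
    excluded_go_terms:
        GO term IDs whose annotated genes (incl. descendants) are dropped
        from DEG sets, e.g. stress-response and metabolism terms.
    rng_seed:
        Master seed; every stochastic stage derives its stream from it.
    """

    fdr_alpha: float = 0.05
    lfc_threshold: float = 1.5
    hotspot_fraction: float = 0.10
    n_random_sets: int = 100
    evidence_required: str = "experimental"
    disease_context: str = "leukemia"
    excluded_go_terms: list[str] = field(default_factory=list)
    rng_seed: int = 0
    # enrichment behaviour (see methods note)
    min_category_size: int = 2
    max_category_size: int | None = None
    filter_enrichment_evidence: bool = False
    hotspots_per_kind: bool = False
    semsim_namespace: str = "biological_process"
    semsim_match_annotation_counts: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if self.lfc_threshold < 0:
            raise ValueError(f"lfc_threshold must be >= 0, got {self.lfc_threshold}")
        if not 0 < self.hotspot_fraction <= 1:
            raise ValueError(
                f"hotspot_fraction must be in (0, 1], got {self.hotspot_fraction}"
            )
        if self.n_random_sets < 1:
            raise ValueError(f"n_random_sets must be >= 1, got {self.n_random_sets}")
        if self.min_category_size < 1:
            raise ValueError("min_category_size must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML config; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
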