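"""End-to-end orchestration of the relapse-GRN workflow.

Per contrast (cell line x drug): differential expression -> DEG thresholds
and functional-term exclusion -> miRNA-target enrichment -> co-regulatory
network with evidence and disease filters -> centralities and hotspots ->
functional-homogeneity test. Across contrasts, DEG-set overlaps (Venn) are
tabulated and the homogeneity p-values are BH-adjusted jointly. Every stage
logs its in/out counts, and the run manifest plus fixed seeds make re-runs
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import PipelineConfig
from .containers import DEGSet
from .diffexpr import (
    call_degs,
    filter_functional_terms,
    nb_wald_test,
    overlap_sets,
    size_factors,
)
from .enrichment import bh_adjust, enrich_mirnas
from .grn import build_grn, centralities, contextualize_disease, flag_hotspots, hotspots
from .semsim import ecdf_table, homogeneity_test
from .simulate import StudyData, _child_seed

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, contrast: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for contrast {contrast!r}: {cause}")
        self.stage = stage
        self.contrast = contrast


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ContrastResult:
    name: str
    de_table: pd.DataFrame
    degs: DEGSet
    removed_by_term_filter: list[str]
    enriched_mirnas: set[str]
    mirna_table: pd.DataFrame
    grn: "object"
    centrality: pd.DataFrame | None
    hotspot_nodes: set[str]
    homogeneity_p: float


def run_pipeline(
    cfg: PipelineConfig,
    study: StudyData,
    out_dir: str | Path,
) -> dict:
    """Run every stage on an in-memory study and write all outputs.

    Returns the run manifest (also written as ``manifest.json``): config
    snapshot, seeds, per-stage set sizes, and every output path. All stages
    are pure functions of (inputs, config, seed), so re-running into a fresh
    directory reproduces each file byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, ContrastResult] = {}
    counts_log: dict[str, dict] = {}

    for i, (name, cm) in enumerate(study.contrasts.items()):
        cdir = out_dir / name
        cdir.mkdir(parents=True, exist_ok=True)
        stage = "differential_expression"
        try:
            factors = size_factors(cm)
            de = nb_wald_test(cm, factors)
            rio.write_table(de.reset_index(), cdir / "de_results.tsv")

            stage = "deg_calling"
            degs = call_degs(de, cfg, provenance=(name,))
            n_before = len(degs)
            removed: list[str] = []
            if cfg.excluded_go_terms:
                degs, removed = filter_functional_terms(
                    degs, study.annot, study.dag, cfg.excluded_go_terms
                )
            rio.write_degset(degs, cdir / "degs.tsv")
            logger.info(
                "%s: %d DEGs (%d removed by functional-term filter)",
                name,
                len(degs),
                len(removed),
            )

            stage = "mirna_enrichment"
            universe = set(de.index)
            mirnas, mtable = enrich_mirnas(degs, study.regdb, universe, cfg)
            rio.write_table(mtable, cdir / "mirna_enrichment.tsv")
            pd.DataFrame({"mirna": sorted(mirnas)}).pipe(
                rio.write_table, cdir / "enriched_mirnas.tsv"
            )

            stage = "grn_construction"
            grn = build_grn(degs, mirnas, study.regdb, cfg)
            edges_before = grn.number_of_edges()
            grn = contextualize_disease(grn, study.disease)
            rio.write_network(grn, cdir / "network.sif")

            stage = "centralities"
            if grn.number_of_nodes():
                cent = centralities(grn)
                hs = hotspots(
                    cent,
                    cfg,
                    kinds={n: d.get("kind", "gene") for n, d in grn.nodes(data=True)},
                )
                flag_hotspots(grn, hs)
                rio.write_table(cent.reset_index(), cdir / "centrality.tsv")
                rio.write_table(
                    pd.DataFrame({"node": sorted(hs)}), cdir / "hotspots.tsv"
                )
            else:
                cent, hs = None, set()

            stage = "homogeneity"
            grn_genes = {
                n for n, d in grn.nodes(data=True) if d.get("kind") == "gene"
            }
            try:
                report = homogeneity_test(
                    grn_genes,
                    study.annot,
                    study.dag,
                    universe,
                    cfg,
                    seed=_child_seed(cfg.rng_seed, 20, i),
                )
                pval = report.pvalue
                ks_stat = report.ks_statistic
                p_asymp = report.pvalue_asymptotic
                rio.write_table(ecdf_table(report), cdir / "homogeneity_ecdf.tsv")
            except ValueError as e:
                logger.warning("%s: homogeneity test skipped (%s)", name, e)
                pval, ks_stat, p_asymp = float("nan"), float("nan"), float("nan")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - report failing stage by name
            raise StageError(stage, name, e) from e

        counts_log[name] = {
            "genes_tested": int(len(cm.gene_ids)),
            "degs_before_term_filter": int(n_before),
            "degs_removed_by_term_filter": len(removed),
            "degs": len(degs),
            "mirnas_tested": int(len(mtable)),
            "enriched_mirnas": len(mirnas),
            "grn_edges_evidence_filtered": int(edges_before),
            "grn_edges_disease_context": int(grn.number_of_edges()),
            "grn_nodes": int(grn.number_of_nodes()),
            "isolated_candidates": len(grn.graph.get("isolated_candidates", [])),
            "hotspots": len(hs),
        }
        results[name] = ContrastResult(
            name=name,
            de_table=de,
            degs=degs,
            removed_by_term_filter=removed,
            enriched_mirnas=mirnas,
            mirna_table=mtable,
            grn=grn,
            centrality=cent,
            hotspot_nodes=hs,
            homogeneity_p=pval,
        )
        counts_log[name]["homogeneity_ks"] = float(ks_stat)
        counts_log[name]["homogeneity_p_asymptotic"] = float(p_asymp)

    # cross-contrast accounting
    if len(results) >= 2:
        venn = overlap_sets({n: r.degs for n, r in results.items()})
        rio.write_table(venn, out_dir / "venn.tsv")

    names = list(results)
    pvals = np.array([results[n].homogeneity_p for n in names], dtype=float)
    ok = np.isfinite(pvals)
    padj = np.full_like(pvals, np.nan)
    if ok.any():
        padj[ok] = bh_adjust(pvals[ok])
    homog = pd.DataFrame(
        {
            "contrast": names,
            "ks_statistic": [counts_log[n]["homogeneity_ks"] for n in names],
            "pvalue": pvals,
            "pvalue_asymptotic": [
                counts_log[n]["homogeneity_p_asymptotic"] for n in names
            ],
            "padj": padj,
            "significant": padj <= cfg.fdr_alpha,
        }
    )
    rio.write_table(homog, out_dir / "homogeneity.tsv")

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.rng_seed,
        "contrasts": names,
        "stage_counts": counts_log,
        "homogeneity": {
            n: {"pvalue": float(p), "padj": float(q)}
            for n, p, q in zip(names, pvals, padj)
        },
        "outputs": sorted(
            str(p.relative_to(out_dir)) for p in out_dir.rglob("*.tsv")
        )
        + sorted(str(p.relative_to(out_dir)) for p in out_dir.rglob("*.sif")),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["results"] = results
    return manifest


def write_study(study: StudyData, out_dir: str | Path) -> dict[str, Path]:
    """Write every synthetic input (plus the truth table) as TSV fixtures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cm in study.contrasts.items():
        cpath = out_dir / f"counts_{name}.tsv"
        gpath = out_dir / f"groups_{name}.tsv"
        rio.write_count_matrix(cm, cpath, gpath)
        paths[f"counts_{name}"] = cpath
        paths[f"groups_{name}"] = gpath
    rio.write_regdb(study.regdb, out_dir / "regdb.tsv")
    paths["regdb"] = out_dir / "regdb.tsv"
    disease_df = pd.DataFrame(
        {
            "entity": sorted(study.disease),
            "entity_type": ["mirna" if e.startswith("mir") else "gene" for e in sorted(study.disease)],
            "disease": "leukemia",
        }
    )
    rio.write_table(disease_df, out_dir / "disease.tsv")
    paths["disease"] = out_dir / "disease.tsv"
    rio.write_go(study.dag, study.annot, out_dir / "go_edges.tsv", out_dir / "go_annot.tsv")
    paths["go_edges"] = out_dir / "go_edges.tsv"
    paths["go_annot"] = out_dir / "go_annot.tsv"
    truth_rows = [
        {"kind": "de_gene", "id": g, "value": f"{lfc:g}"}
        for g, lfc in sorted(study.truth.de_genes.items())
    ]
    truth_rows += [
        {"kind": "enriched_mirna", "id": m, "value": ""}
        for m in sorted(study.truth.enriched_mirnas)
    ]
    truth_rows += [
        {"kind": "module_gene", "id": g, "value": ""}
        for g in sorted(study.truth.homogeneous_module)
    ]
    rio.write_table(pd.DataFrame(truth_rows), out_dir / "truth.tsv")
    paths["truth"] = out_dir / "truth.tsv"
    return paths


def load_study(
    counts_paths: dict[str, tuple[str | Path, str | Path]],
    regdb_path: str | Path,
    disease_path: str | Path,
    go_edges_path: str | Path,
    go_annot_path: str | Path,
    disease_context: str = "leukemia",
) -> StudyData:
    """Assemble a StudyData from on-disk inputs (the file-based entry path)."""
    contrasts = {
        name: rio.read_count_matrix(c, g) for name, (c, g) in counts_paths.items()
    }
    regdb = rio.read_regdb(regdb_path)
    assoc = rio.read_disease(disease_path).for_disease(disease_context)
    dag, annot = rio.read_go(go_edges_path, go_annot_path)
    from .simulate import SyntheticTruth

    return StudyData(
        contrasts=contrasts,
        regdb=regdb,
        disease=assoc,
        dag=dag,
        annot=annot,
        truth=SyntheticTruth(seed=-1),
        per_contrast_truth={},
        planted_mirna={},
    )
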