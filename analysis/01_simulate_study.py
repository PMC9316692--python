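#!/usr/bin/env python
"""Generate the synthetic relapse study and write all pipeline inputs.

Produces, under results/inputs/: one count matrix + group table per
contrast, the shared regulatory-interaction database, the disease list, the
GO DAG with annotations, and truth.tsv recording what was planted (DE genes
with signed log2FC, the enriched miRNA and driver hub per contrast, the
homogeneous GO modules).
"""

from pathlib import Path

from relapsegrn import simulate_study, write_study

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    study = simulate_study(SEED)
    paths = write_study(study, OUT)
    print(f"seed {SEED}: wrote {len(paths)} files under {OUT}")
    for name, cm in study.contrasts.items():
        t = study.per_contrast_truth[name]
        print(
            f"  contrast {name}: {cm.counts.shape[0]} genes x "
            f"{cm.counts.shape[1]} samples, {len(t.de_genes)} planted DE genes, "
            f"planted miRNA {study.planted_mirna[name]}, "
            f"planted hub {study.planted_hub[name]}"
        )
    print(f"  regulatory DB: {len(study.regdb)} interactions")
    print(f"  disease list: {len(study.disease)} associated entities")
    print(f"  GO: {len(study.dag.graph)} terms, {len(study.annot)} annotated genes")


if __name__ == "__main__":
    main()
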