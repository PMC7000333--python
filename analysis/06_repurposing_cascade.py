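#!/usr/bin/env python
"""Run the drug-target prioritization cascade on the synthetic bioactivity
database: quality filter, ortholog mapping, progression intersect, clinical
phase, treatment-normalized restriction, ATC and mode-of-action filters,
and stage prioritization."""

import pandas as pd
from common import DATA, outdir

from pkdrx import cascade as casc
from pkdrx import io as pio


def main() -> None:
    bio = pio.read_bioactivities_csv(DATA / "bioactivities.csv")
    cpds = pio.read_compounds_csv(DATA / "compounds.csv")
    ortho = pio.read_orthologs_tsv(DATA / "orthologs.tsv")
    stage_genes = pio.read_stage_genes_tsv(outdir() / "stage_genes.tsv")
    normalized = set(pd.read_csv(outdir() / "normalized_genes.tsv", sep="\t")["gene"])

    res = casc.run_cascade(bio, cpds, stage_genes, ortho, normalized)
    print("cascade step survivors (targets / compounds):")
    for step in res.steps:
        print(f"  {step.name:<12} {step.n_targets:>4} / {step.n_compounds:>4}")
    if not res.ortholog_log.empty:
        print("ortholog mapping exclusions:")
        print(res.ortholog_log.groupby("reason").size().to_string())
    print(f"final ranked candidates ({len(res.final)} targets):")
    print(res.final[["target", "stage", "direction", "priority", "max_pchembl", "n_compounds"]]
          .to_string(index=False))

    out = outdir()
    res.final.to_csv(out / "candidates.tsv", sep="\t", index=False)
    pio.write_json([s.to_dict() for s in res.steps], out / "cascade_steps.json")
    print(f"wrote candidates.tsv, cascade_steps.json -> {out}")


if __name__ == "__main__":
    main()
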