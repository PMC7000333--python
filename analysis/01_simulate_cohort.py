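#!/usr/bin/env python
"""Generate the synthetic study inputs: RNA-seq cohort, treatment arms,
bioactivity database and ortholog map, all written as plain-text tables."""

from common import outdir, study_config

from pkdrx import io as pio
from pkdrx import simulate as sim


def main() -> None:
    cfg = study_config()
    counts, info, truth = sim.simulate_cohort(cfg)
    bio, cpds, ortho, truth = sim.simulate_bioactivity_db(cfg, truth)

    data = outdir("data")
    pio.write_counts_tsv(counts, data / "counts.tsv")
    pio.write_metadata_tsv(info, data / "samples.tsv")
    pio.write_bioactivities_csv(bio, data / "bioactivities.csv")
    pio.write_compounds_csv(cpds, data / "compounds.csv")
    pio.write_orthologs_tsv(ortho, data / "orthologs.tsv")
    pio.write_json(
        {
            "seed": cfg.seed,
            "progression_genes": sorted(truth.progression_genes),
            "aberrant_genes": truth.aberrant_genes,
            "normalized_by_arm": {k: sorted(v) for k, v in truth.normalized_by_arm.items()},
            "cascade_survivors": {
                s: {k: sorted(v) for k, v in d.items()} for s, d in truth.cascade_survivors.items()
            },
        },
        data / "ground_truth.json",
    )

    print(f"cohort: {counts.shape[0]} genes x {counts.shape[1]} samples (seed {cfg.seed})")
    print(f"planted: {len(truth.progression_genes)} progression genes in "
          f"{len(cfg.archetypes)} archetypes + {len(truth.aberrant_genes)} aberrant genes")
    print(f"treatment arms: {[a.name for a in cfg.treatment_arms]} "
          f"normalizing {len(truth.normalized_genes)} genes")
    print(f"bioactivities: {len(bio)} records, {cpds.shape[0]} compounds, "
          f"{bio['target_id'].nunique()} targets -> inputs in {data}")


if __name__ == "__main__":
    main()
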