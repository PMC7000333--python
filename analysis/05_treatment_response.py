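#!/usr/bin/env python
"""Treated-vs-untreated differential expression per drug arm, balancing of
the significant lists to a common size, and selection of progression genes
normalized by at least one treatment."""

from common import DATA, outdir, study_config

from pkdrx import clusters as clu
from pkdrx import expression as expr
from pkdrx import io as pio
from pkdrx import simulate as sim
from pkdrx import treatment as trt


def main() -> None:
    counts = pio.read_counts_tsv(DATA / "counts.tsv")
    info = pio.read_metadata_tsv(DATA / "samples.tsv")
    em = expr.normalize(counts)
    kept = expr.noise_filter(expr.compute_cpm(counts, tmm=em.tmm))
    em = expr.ExpressionMatrix(logcpm=em.logcpm.loc[kept], lib_size=em.lib_size, tmm=em.tmm)
    union, _ = clu.progression_deg_union(em, info)
    prof = clu.relative_profiles(em, info, genes=sorted(union))
    asn = clu.flag_aberrant_clusters(clu.hierarchical_cluster(prof, k=15), em, info)
    groups = clu.assign_stage(asn)

    meta = info.set_index("sample_id")
    arms = []
    for name in sorted(set(meta["treatment"]) - {"none"}):
        treated = list(meta.index[meta["treatment"] == name])
        comparator = set(meta.loc[treated, "group"])
        untreated = list(meta.index[(meta["treatment"] == "none") & meta["group"].isin(comparator)])
        arms.append(trt.treatment_de(em, treated, untreated, name, p_threshold=0.05))
    for a in arms:
        print(f"{a.name}: {a.n_significant} significant genes (p < 0.05)")
    arms = trt.balance_lists(arms)
    print(f"balanced list size (smallest arm): {arms[0].balanced_size}")

    res = trt.normalized_genes(groups, arms)
    print(f"progression genes normalized by >= 1 treatment: {len(res.genes)} "
          f"of {len(groups.all_genes())}")
    _, _, truth = sim.simulate_cohort(study_config())
    planted = truth.normalized_genes
    print(f"vs planted truth: recall {len(res.genes & planted)/len(planted):.2f}, "
          f"precision {len(res.genes & planted)/max(len(res.genes),1):.2f}")

    frac = trt.cluster_response_fractions(asn, arms)
    print("fraction of cluster genes affected per arm (first rows):")
    print(frac.head(6).round(2).to_string())

    out = outdir()
    res.table.to_csv(out / "normalized_genes.tsv", sep="\t", index=False)
    frac.to_csv(out / "cluster_response_fractions.tsv", sep="\t", index_label="cluster")
    print(f"wrote normalized_genes.tsv, cluster_response_fractions.tsv -> {out}")


if __name__ == "__main__":
    main()
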