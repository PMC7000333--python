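#!/usr/bin/env python
"""Normalize the count matrix (TMM + log2-CPM), apply the noise filter and
summarize sample structure with PCA."""

import pandas as pd
from common import DATA, outdir

from pkdrx import expression as expr
from pkdrx import io as pio


def main() -> None:
    counts = pio.read_counts_tsv(DATA / "counts.tsv")
    info = pio.read_metadata_tsv(DATA / "samples.tsv")

    em = expr.normalize(counts)
    cpm = expr.compute_cpm(counts, tmm=em.tmm)
    kept = expr.noise_filter(cpm, threshold=2.0, fraction=0.5)
    print(f"noise filter (cpm < 2 in > 50% of samples): kept {len(kept)}/{counts.shape[0]} genes")
    print(f"TMM factors: min {em.tmm.min():.3g}, max {em.tmm.max():.3g} (geometric mean 1; "
          "the tiny minimum is the spiked sample whose library the artifact genes inflate)")

    meta = info.set_index("sample_id")
    untreated = [s for s in counts.columns if meta.loc[s, "treatment"] == "none"]
    res = expr.pca(em.logcpm.loc[kept, untreated])
    vf = res.variance_fraction[:3]
    print(f"PCA of progression samples: PC1 {vf[0]:.1%}, PC2 {vf[1]:.1%}, PC3 {vf[2]:.1%} of variance")

    out = outdir()
    em.logcpm.loc[kept].to_csv(out / "logcpm_filtered.tsv", sep="\t", index_label="gene")
    scores = res.scores.iloc[:, :3].join(meta[["group", "kw_bw"]])
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    pd.Series(res.variance_fraction, name="variance_fraction").to_csv(
        out / "pca_variance.tsv", sep="\t", index_label="component"
    )
    print(f"wrote logcpm_filtered.tsv, pca_scores.tsv, pca_variance.tsv -> {out}")


if __name__ == "__main__":
    main()
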