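"""Gene-set overlap and annotation statistics for stage gene groups.

The representation factor (RF) quantifies overlap between two gene sets
against the expectation for independent draws from a shared background:
RF = observed overlap / (n1 * n2 / N).  RF > 1 means more overlap than
expected for independent sets, RF = 1 the independent expectation, RF < 1
less.  An exact hypergeometric tail probability accompanies it.

Over-representation analysis against user-supplied GMT pathway collections
uses the one-sided hypergeometric test with the noise-filtered expressed
genes as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import StageGeneGroups


class StatsError(ValueError):
    pass


@dataclass
class RFResult:
    overlap: int
    expected_overlap: float
    representation_factor: float
    hypergeometric_p: float
    n_a: int
    n_b: int
    n_background: int


def representation_factor(set_a, set_b, background) -> RFResult:
    """Representation factor of two gene sets over a common background.

    Both sets must be subsets of the background.  The p-value is the exact
    hypergeometric probability of observing at least the given overlap.
    """
    a, b, bg = set(set_a), set(set_b), set(background)
    if not bg:
        raise StatsError("background is empty")
    stray = sorted((a | b) - bg)
    if stray:
        raise StatsError(f"sets contain genes outside the background: {stray[:10]}")
    n, n1, n2 = len(bg), len(a), len(b)
    k = len(a & b)
    expected = n1 * n2 / n
    rf = k / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(k - 1, n, n1, n2)) if min(n1, n2) > 0 else 1.0
    return RFResult(k, expected, rf, p, n1, n2, n)


def replication_matrix(
    stage_groups: StageGeneGroups,
    signatures: dict[str, set],
    background,
) -> pd.DataFrame:
    """RF of each stage gene group against each external signature.

    Rows are stages, columns signatures; empty signatures yield NaN.
    """
    bg = set(background)
    rows = {}
    for stage, genes in stage_groups.genes.items():
        row = {}
        for name, sig in signatures.items():
            sig = set(sig) & bg
            if not sig:
                row[name] = np.nan
                continue
            row[name] = representation_factor(genes & bg, sig, bg).representation_factor
        rows[stage] = row
    return pd.DataFrame(rows).T


def spearman_kwbw(
    logcpm: pd.DataFrame,
    assignment,
    sample_info: pd.DataFrame,
    control_group: str = "WT",
) -> pd.Series:
    """Average Spearman correlation of cluster gene expression with 2KW/BW.

    For each retained cluster, each member gene's expression across the
    untreated mutant samples is rank-correlated (mid-ranks on ties) with the
    two-kidney-weight/body-weight ratio; the cluster value is the mean over
    genes.
    """
    info = sample_info.set_index("sample_id") if "sample_id" in sample_info.columns else sample_info
    if "treatment" in info.columns:
        info = info[info["treatment"] == "none"]
    mut = info[(info["group"] != control_group) & info["kw_bw"].notna()]
    if len(mut) < 3:
        raise StatsError("need at least 3 mutant samples with kw_bw")
    kwbw = mut["kw_bw"].astype(float)
    if kwbw.nunique() == 1:
        raise StatsError("kw_bw is constant; Spearman correlation undefined")
    out = {}
    for c in assignment.retained():
        rhos = []
        for g in assignment.genes_in(c):
            x = logcpm.loc[g, list(mut.index)].to_numpy(float)
            if np.all(x == x[0]):
                continue  # constant gene: correlation undefined, skip
            rho, _ = stats.spearmanr(x, kwbw.to_numpy())
            rhos.append(rho)
        out[c] = float(np.mean(rhos)) if rhos else np.nan
    return pd.Series(out, name="spearman_kwbw")


def overrepresentation(
    gene_set,
    pathways: dict[str, set],
    background,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    Pathways are intersected with the background before testing; a BH
    column is appended over all tested terms; only terms with raw
    p < ``p_threshold`` are returned, sorted by p.
    """
    from .expression import bh_fdr

    genes = set(gene_set)
    bg = set(background)
    if not genes:
        raise StatsError("empty gene set")
    stray = sorted(genes - bg)
    if stray:
        raise StatsError(f"gene set outside background: {stray[:10]}")
    n, n_set = len(bg), len(genes)
    rows = []
    for term in sorted(pathways):
        pw = set(pathways[term]) & bg
        if not pw:
            continue
        k = len(genes & pw)
        p = float(stats.hypergeom.sf(k - 1, n, n_set, len(pw)))
        rows.append({"term": term, "pathway_size": len(pw), "overlap": k, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "pathway_size", "overlap", "p", "fdr"])
    tab = pd.DataFrame(rows)
    tab["fdr"] = bh_fdr(tab["p"].to_numpy())
    tab = tab[tab["p"] < p_threshold].sort_values(["p", "term"]).reset_index(drop=True)
    return tab
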