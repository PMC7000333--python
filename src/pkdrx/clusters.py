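"""Progression gene clustering and disease-stage grouping.

Genes differentially expressed anywhere along disease progression are
clustered by their time-course profile relative to wild-type control,
clusters whose apparent signal is driven by a single sample are flagged as
aberrant, and the retained clusters are grouped into early / moderate /
advanced disease-stage gene sets with an up/down direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression import ExpressionMatrix, ExpressionError, differential_expression

STAGES = ("early", "moderate", "advanced")
DEFAULT_STAGE_WINDOWS = {"early": (2, 3, 6), "moderate": (11, 12), "advanced": (15,)}


class ClusterError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    """Gene-to-cluster map with per-cluster mean relative profiles.

    ``profiles`` is clusters x timepoints (mean log2 ratio to control);
    ``qc_flag`` maps cluster id -> "retained" | "aberrant".
    """

    labels: pd.Series                      # gene -> cluster id (1..k)
    profiles: pd.DataFrame                 # cluster id x timepoint
    sizes: pd.Series                       # cluster id -> gene count
    qc_flag: dict[int, str] = field(default_factory=dict)

    def retained(self) -> list[int]:
        return [c for c in self.profiles.index if self.qc_flag.get(c, "retained") == "retained"]

    def genes_in(self, cluster: int) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster])


@dataclass
class StageGeneGroups:
    """Early/moderate/advanced progression gene groups with directions."""

    genes: dict[str, set]                  # stage -> gene set
    direction: pd.Series                   # gene -> "up" | "down"
    cluster_stage: dict[int, str]          # retained cluster id -> stage
    cluster_direction: dict[int, str] = field(default_factory=dict)

    def all_genes(self) -> set:
        out = set()
        for s in self.genes.values():
            out |= s
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "stage": stage, "direction": self.direction[g]}
            for stage, genes in self.genes.items()
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "stage", "direction"])


# ---------------------------------------------------------------------------


def relative_profiles(
    expr: ExpressionMatrix | pd.DataFrame,
    sample_info: pd.DataFrame,
    genes: list[str] | None = None,
    control_group: str = "WT",
) -> pd.DataFrame:
    """Mean log2-CPM of each mutant group minus the control mean, per gene.

    Returns genes x timepoints (columns are the weeks-post-induction of the
    untreated mutant groups, ascending).
    """
    logcpm = expr.logcpm if isinstance(expr, ExpressionMatrix) else expr
    if genes is not None:
        logcpm = logcpm.loc[list(genes)]
    info = sample_info.set_index("sample_id") if "sample_id" in sample_info.columns else sample_info
    untreated = info[info.get("treatment", "none") == "none"] if "treatment" in info.columns else info
    wt = untreated.index[untreated["group"] == control_group]
    if len(wt) == 0:
        raise ClusterError(f"no control samples with group={control_group!r}")
    base = logcpm[list(wt)].mean(axis=1)
    cols = {}
    mutant = untreated[untreated["group"] != control_group]
    for week, sub in mutant.groupby("weeks_post_induction"):
        cols[float(week)] = logcpm[list(sub.index)].mean(axis=1) - base
    prof = pd.DataFrame(cols)
    return prof[sorted(prof.columns)]


def progression_deg_union(
    expr: ExpressionMatrix,
    sample_info: pd.DataFrame,
    fdr_threshold: float = 0.005,
    control_group: str = "WT",
) -> tuple[set, dict[str, pd.DataFrame]]:
    """Union of genes significant in any pairwise progression contrast.

    All pairwise contrasts among the untreated groups (control included) are
    tested; a gene enters the union if its BH FDR is below the threshold in
    at least one contrast.  Returns the union and the per-contrast tables.
    """
    info = sample_info.set_index("sample_id") if "sample_id" in sample_info.columns else sample_info
    if "treatment" in info.columns:
        info = info[info["treatment"] == "none"]
    groups = {g: list(idx) for g, idx in info.groupby("group").groups.items()}
    if len(groups) < 2:
        raise ClusterError("need at least 2 groups for progression contrasts")
    union: set = set()
    tables: dict[str, pd.DataFrame] = {}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        label = f"{ga}_vs_{gb}"
        tab = differential_expression(expr, groups[ga], groups[gb], contrast=label)
        tables[label] = tab
        union |= set(tab.index[tab["fdr"] < fdr_threshold])
    return union, tables


def hierarchical_cluster(
    profiles: pd.DataFrame, k: int = 15, metric: str = "euclidean", linkage: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering of gene profiles, tree cut into exactly k.

    Genes are sorted lexicographically first so the result is invariant to
    input order; cluster ids are 1..k in order of first member gene.
    """
    if profiles.isna().any().any():
        raise ClusterError("profiles contain missing values")
    profiles = profiles.loc[sorted(profiles.index)]
    n = profiles.shape[0]
    if k > n:
        raise ClusterError(f"k={k} exceeds number of genes {n}")
    if n == 0:
        raise ClusterError("no genes to cluster")
    z = hierarchy.linkage(pdist(profiles.to_numpy(float), metric=metric), method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # relabel deterministically by first occurrence in gene-sorted order
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[lab] for lab in raw], index=profiles.index, name="cluster")
    prof_rows = {}
    sizes = {}
    for c in sorted(set(labels)):
        members = labels.index[labels == c]
        prof_rows[c] = profiles.loc[members].mean(axis=0)
        sizes[c] = len(members)
    return ClusterAssignment(
        labels=labels,
        profiles=pd.DataFrame(prof_rows).T,
        sizes=pd.Series(sizes),
        qc_flag={c: "retained" for c in sizes},
    )


def flag_aberrant_clusters(
    assignment: ClusterAssignment,
    expr: ExpressionMatrix | pd.DataFrame,
    sample_info: pd.DataFrame,
    dominance: float = 0.5,
    control_group: str = "WT",
) -> ClusterAssignment:
    """Flag clusters whose profile is dominated by a single sample.

    For each cluster the mean relative profile is recomputed leaving out one
    mutant sample at a time; the cluster is flagged aberrant iff some single
    omission shrinks the profile's maximum |log2 ratio| by more than
    ``dominance`` as a fraction of the full-profile maximum.
    """
    logcpm = expr.logcpm if isinstance(expr, ExpressionMatrix) else expr
    info = sample_info.set_index("sample_id") if "sample_id" in sample_info.columns else sample_info
    if "treatment" in info.columns:
        info = info[info["treatment"] == "none"]
    wt = info.index[info["group"] == control_group]
    mutant = info[info["group"] != control_group]
    qc = dict(assignment.qc_flag)
    for c in assignment.profiles.index:
        members = assignment.genes_in(c)
        base = logcpm.loc[members, list(wt)].mean(axis=1)
        rel = logcpm.loc[members].sub(base, axis=0)  # per-sample relative values
        # cluster-mean relative value per sample, then group means per timepoint
        per_sample = rel[list(mutant.index)].mean(axis=0)
        week = mutant["weeks_post_induction"].astype(float)
        full = per_sample.groupby(week).mean()
        full_max = float(full.abs().max())
        if full_max == 0:
            continue
        flagged = False
        for s in mutant.index:
            keep = [x for x in mutant.index if x != s]
            loo = per_sample[keep].groupby(week[keep]).mean()
            drop = (full_max - float(loo.abs().max())) / full_max
            if drop > dominance:
                flagged = True
                break
        if flagged:
            qc[c] = "aberrant"
    return ClusterAssignment(
        labels=assignment.labels, profiles=assignment.profiles, sizes=assignment.sizes, qc_flag=qc
    )


def assign_stage(
    assignment: ClusterAssignment,
    stage_windows: dict[str, tuple] | None = None,
) -> StageGeneGroups:
    """Group retained clusters into stage gene sets by profile peak.

    A cluster's stage is the window containing the timepoint at which its
    mean |log2 ratio| peaks; its direction is the sign of the mean ratio at
    that peak.  Genes inherit their cluster's stage and direction.
    """
    windows = stage_windows or DEFAULT_STAGE_WINDOWS
    tp_to_stage: dict[float, str] = {}
    for stage, tps in windows.items():
        for t in tps:
            tp_to_stage[float(t)] = stage
    genes: dict[str, set] = {s: set() for s in windows}
    direction = {}
    cluster_stage = {}
    cluster_direction = {}
    for c in assignment.retained():
        prof = assignment.profiles.loc[c]
        peak_t = float(prof.abs().idxmax())
        if peak_t not in tp_to_stage:
            raise ClusterError(f"timepoint {peak_t} outside all stage windows")
        stage = tp_to_stage[peak_t]
        d = "up" if prof[peak_t] >= 0 else "down"
        cluster_stage[c] = stage
        cluster_direction[c] = d
        for g in assignment.genes_in(c):
            genes[stage].add(g)
            direction[g] = d
    return StageGeneGroups(
        genes=genes,
        direction=pd.Series(direction, dtype=object),
        cluster_stage=cluster_stage,
        cluster_direction=cluster_direction,
    )
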