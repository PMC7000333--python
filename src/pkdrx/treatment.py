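"""Treated-vs-untreated response: list balancing and normalized genes.

Each drug arm is compared to its own matched untreated group with the same
moderated t-test used for progression contrasts, but gated on the raw
p-value (p < 0.05).  Because the arms differ widely in how many genes they
perturb, the per-arm significant lists are truncated to a common size — the
smallest arm's count — before asking which progression genes were
"normalized": moved by at least one treatment in the direction opposite to
their disease-progression dysregulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clusters import ClusterAssignment, StageGeneGroups
from .expression import ExpressionMatrix, differential_expression


class TreatmentError(ValueError):
    pass


@dataclass
class TreatmentDEG:
    """Per-arm differential expression summary.

    ``ranked`` holds the significant genes sorted ascending by p (ties by
    larger |log2fc|, then gene id); ``balanced`` is the prefix retained
    after list balancing.
    """

    name: str
    table: pd.DataFrame            # full DE table (log2fc, t, p, fdr)
    ranked: list[str]              # significant genes, p-ascending
    n_significant: int
    balanced_size: int | None = None

    @property
    def balanced(self) -> list[str]:
        if self.balanced_size is None:
            return list(self.ranked)
        return self.ranked[: self.balanced_size]

    def direction(self, gene: str) -> str:
        return "up" if self.table.loc[gene, "log2fc"] > 0 else "down"


@dataclass
class NormalizedGeneSet:
    """Progression genes counteracted by at least one drug treatment."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene, stage, progression_direction, treatments (;-joined), treatment_direction

    @property
    def genes(self) -> set:
        if self.table.empty:
            return set()
        return set(self.table["gene"])


def treatment_de(
    expr: ExpressionMatrix,
    treated: list[str],
    untreated: list[str],
    name: str,
    p_threshold: float = 0.05,
) -> TreatmentDEG:
    """Treated-vs-untreated moderated t per gene; significance on raw p."""
    tab = differential_expression(expr, treated, untreated, contrast=f"{name}_vs_untreated")
    sig = tab[tab["p"] < p_threshold].copy()
    sig["abs_lfc"] = sig["log2fc"].abs()
    # deterministic ordering: p asc, |lfc| desc, gene id asc
    sig = sig.assign(_g=sig.index).sort_values(
        by=["p", "abs_lfc", "_g"], ascending=[True, False, True], kind="mergesort"
    )
    ranked = list(sig.index)
    return TreatmentDEG(name=name, table=tab, ranked=ranked, n_significant=len(ranked))


def balance_lists(arms: list[TreatmentDEG]) -> list[TreatmentDEG]:
    """Truncate every arm's ranked list to the smallest arm's count.

    The common size is the minimum n_significant over arms; each list keeps
    its p-ranked prefix (tie-break at the cutoff already applied in
    :func:`treatment_de`: larger |log2fc|, then lexicographic gene id).
    """
    if not arms:
        raise TreatmentError("no treatment arms supplied")
    for arm in arms:
        if arm.n_significant < 1:
            raise TreatmentError(f"arm {arm.name!r} has zero significant genes")
    size = min(arm.n_significant for arm in arms)
    return [
        TreatmentDEG(
            name=a.name, table=a.table, ranked=a.ranked, n_significant=a.n_significant,
            balanced_size=size,
        )
        for a in arms
    ]


def normalized_genes(progression: StageGeneGroups, arms: list[TreatmentDEG]) -> NormalizedGeneSet:
    """Progression genes whose dysregulation is opposed by >=1 treatment.

    A gene qualifies iff it belongs to a stage gene group and appears in at
    least one arm's balanced list with a treated-vs-untreated log2FC of the
    opposite sign to its progression direction (up-regulated genes less
    increased, down-regulated genes less decreased).
    """
    stage_of = {}
    for stage, genes in progression.genes.items():
        for g in genes:
            stage_of[g] = stage
    rows = []
    for g in sorted(stage_of):
        pdir = progression.direction.get(g)
        if pdir not in ("up", "down"):
            raise TreatmentError(f"gene {g!r} has no progression direction")
        supporting = []
        tdirs = set()
        for arm in arms:
            if g in arm.balanced:
                tdir = arm.direction(g)
                if tdir != pdir:  # opposing sign counteracts the dysregulation
                    supporting.append(arm.name)
                    tdirs.add(tdir)
        if supporting:
            rows.append(
                {
                    "gene": g,
                    "stage": stage_of[g],
                    "progression_direction": pdir,
                    "treatments": ";".join(supporting),
                    "treatment_direction": ";".join(sorted(tdirs)),
                }
            )
    cols = ["gene", "stage", "progression_direction", "treatments", "treatment_direction"]
    return NormalizedGeneSet(table=pd.DataFrame(rows, columns=cols))


def cluster_response_fractions(
    assignment: ClusterAssignment, arms: list[TreatmentDEG]
) -> pd.DataFrame:
    """Fraction of each retained cluster's genes hit by each arm (raw p gate).

    Mirrors the per-cluster drug-response bars: the share of a cluster's
    genes present in the arm's full significant set.
    """
    rows = {}
    for c in assignment.retained():
        members = set(assignment.genes_in(c))
        n = len(members)
        rows[c] = {
            arm.name: (len(members & set(arm.ranked)) / n if n else 0.0) for arm in arms
        }
    return pd.DataFrame(rows).T.sort_index()
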