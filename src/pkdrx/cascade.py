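"""Drug-target acquisition and prioritization cascade.

Starting from a ChEMBL-style bioactivity table (compound, target, pChEMBL,
assay confidence, organism) and compound annotations (max clinical phase,
ATC codes, mode of action), the cascade narrows candidate repurposing drugs
for ADPKD in the following order, keeping per-step provenance:

1. quality        — confidence 9 (direct single protein target), pChEMBL
                    present, human target, >= 30 measurements per target
2. orthologs      — mouse progression genes mapped one-to-one to human
3. intersect      — targets restricted to progression genes
4. phase          — compounds tested in clinical phases 2, 3 or 4
5. normalized     — targets restricted to treatment-normalized genes
6. atc            — antineoplastic compounds (ATC prefix L01) removed
7. moa            — pairs whose mode of action would push the target
                    further in its disease direction removed; unknown kept
8. prioritize     — targets tiered early < moderate < advanced, then by
                    best pChEMBL

Each filter returns its surviving records plus a step report with counts
and the identifiers it removed, so the final table is fully traceable.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

RECORD_COLUMNS = ["compound_id", "target_id", "target_organism", "pchembl", "confidence_score", "assay_id"]
ACTIONS_UP = frozenset({"agonist", "activator"})       # increase target activity
ACTIONS_DOWN = frozenset({"antagonist", "inhibitor"})  # decrease target activity
KNOWN_ACTIONS = ACTIONS_UP | ACTIONS_DOWN | {"unknown"}
ATC_PATTERN = re.compile(r"^[A-Z][0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?$")
STAGE_PRIORITY = {"early": 1, "moderate": 2, "advanced": 3}


class CascadeError(ValueError):
    pass


@dataclass
class StepReport:
    name: str
    n_targets: int
    n_compounds: int
    removed_targets: list[str] = field(default_factory=list)
    removed_compounds: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "step": self.name,
            "n_targets": self.n_targets,
            "n_compounds": self.n_compounds,
            "removed_targets": sorted(self.removed_targets),
            "removed_compounds": sorted(self.removed_compounds),
        }


@dataclass
class CascadeResult:
    steps: list[StepReport]
    final: pd.DataFrame          # target, stage, direction, priority, max_pchembl, n_compounds, compounds
    records: pd.DataFrame        # surviving bioactivity records
    ortholog_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def step_counts(self) -> dict[str, dict[str, int]]:
        return {s.name: {"targets": s.n_targets, "compounds": s.n_compounds} for s in self.steps}


def _survivors(records: pd.DataFrame) -> tuple[set, set]:
    return set(records["target_id"]), set(records["compound_id"])


def _report(name: str, before: pd.DataFrame, after: pd.DataFrame) -> StepReport:
    t0, c0 = _survivors(before)
    t1, c1 = _survivors(after)
    return StepReport(name, len(t1), len(c1), sorted(t0 - t1), sorted(c0 - c1))


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise CascadeError(f"bioactivity table missing columns: {missing}")
    bad = records.index[records["target_id"].isna() | records["compound_id"].isna()]
    if len(bad):
        raise CascadeError(f"malformed record(s) missing target or compound at rows {list(bad[:10])}")
    return records


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def quality_filter(
    records: pd.DataFrame, min_measurements: int = 30, human_label: str = "Homo sapiens"
) -> tuple[pd.DataFrame, StepReport]:
    """High-quality direct-target bioactivities.

    Keeps records with confidence score 9, a pChEMBL value and a human
    target, then drops targets left with fewer than ``min_measurements``
    qualifying records (>= 30 keeps exactly 30).
    """
    validate_records(records)
    if records.empty:
        raise CascadeError("empty bioactivity table")
    ok = (
        (records["confidence_score"] == 9)
        & records["pchembl"].notna()
        & (records["target_organism"].str.lower() == human_label.lower())
    )
    kept = records[ok]
    counts = kept.groupby("target_id").size()
    good_targets = set(counts.index[counts >= min_measurements])
    out = kept[kept["target_id"].isin(good_targets)]
    return out, _report("quality", records, out)


def map_orthologs(
    mouse_genes: pd.DataFrame, ortholog_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transfer stage/direction annotation from mouse genes to human symbols.

    ``mouse_genes`` needs columns gene, stage, direction; ``ortholog_map``
    columns mouse_id, human_symbol.  Mouse genes absent from the map or
    mapping to more than one human symbol are dropped and logged with a
    reason code (unmapped / multi-mapped).
    """
    for col in ("gene", "stage", "direction"):
        if col not in mouse_genes.columns:
            raise CascadeError(f"mouse gene table missing column {col!r}")
    if ortholog_map.empty:
        raise CascadeError("empty ortholog map")
    pairs = ortholog_map.drop_duplicates()
    n_human = pairs.groupby("mouse_id")["human_symbol"].nunique()
    rows, log = [], []
    for _, row in mouse_genes.iterrows():
        g = row["gene"]
        if g not in n_human.index:
            log.append({"gene": g, "reason": "unmapped"})
        elif n_human[g] > 1:
            log.append({"gene": g, "reason": "multi-mapped"})
        else:
            human = pairs.loc[pairs["mouse_id"] == g, "human_symbol"].iloc[0]
            rows.append({"gene": human, "mouse_gene": g, "stage": row["stage"], "direction": row["direction"]})
    human_df = pd.DataFrame(rows, columns=["gene", "mouse_gene", "stage", "direction"])
    log_df = pd.DataFrame(log, columns=["gene", "reason"])
    return human_df, log_df


def intersect_targets(
    records: pd.DataFrame, progression_genes: set
) -> tuple[pd.DataFrame, StepReport]:
    """Restrict bioactivities to targets that are progression genes."""
    out = records[records["target_id"].isin(set(progression_genes))]
    return out, _report("intersect", records, out)


def phase_filter(
    records: pd.DataFrame, compounds: pd.DataFrame, min_phase: int = 2
) -> tuple[pd.DataFrame, StepReport]:
    """Keep compounds tested in clinical phase >= min_phase.

    Compounds missing from the annotation table count as phase 0
    (fail-closed); targets left without any record drop out.
    """
    phase = compounds.set_index("compound_id")["max_phase"].to_dict()
    ok = records["compound_id"].map(lambda c: phase.get(c, 0) >= min_phase).astype(bool)
    out = records[ok]
    return out, _report("phase", records, out)


def normalized_target_filter(
    records: pd.DataFrame, normalized_genes: set
) -> tuple[pd.DataFrame, StepReport]:
    """Restrict targets to treatment-normalized progression genes."""
    out = records[records["target_id"].isin(set(normalized_genes))]
    return out, _report("normalized", records, out)


def _valid_atc_codes(codes, compound_id: str) -> list[str]:
    valid = []
    for code in codes:
        if ATC_PATTERN.match(code):
            valid.append(code)
        else:
            warnings.warn(f"ignoring invalid ATC code {code!r} on compound {compound_id}")
    return valid


def atc_filter(
    records: pd.DataFrame,
    compounds: pd.DataFrame,
    excluded_prefixes: tuple[str, ...] = ("L01",),
) -> tuple[pd.DataFrame, StepReport]:
    """Remove compounds with any ATC code under an excluded prefix.

    Default exclusion is the antineoplastic class L01; compounds with no
    ATC annotation are kept (the class is unknown, not antineoplastic).
    """
    codes = {
        row["compound_id"]: _valid_atc_codes(row.get("atc_codes") or [], row["compound_id"])
        for _, row in compounds.iterrows()
    }

    def bad(cpd: str) -> bool:
        return any(code.startswith(p) for code in codes.get(cpd, []) for p in excluded_prefixes)

    out = records[~records["compound_id"].map(bad).astype(bool)]
    return out, _report("atc", records, out)


def moa_filter(
    records: pd.DataFrame,
    compounds: pd.DataFrame,
    target_direction: dict[str, str],
) -> tuple[pd.DataFrame, StepReport]:
    """Drop pairs whose known mode of action aggravates the dysregulation.

    A pair is conflicting when the drug activates an up-regulated target or
    inhibits a down-regulated one.  Pairs with no known action are kept.
    """
    moa: dict[tuple[str, str], str] = {}
    for _, row in compounds.iterrows():
        for entry in row.get("moa") or []:
            tgt, action = entry
            action = str(action).strip().lower()
            if action not in KNOWN_ACTIONS:
                raise CascadeError(f"unrecognized mode-of-action term {action!r}")
            moa[(row["compound_id"], tgt)] = action

    def conflict(row) -> bool:
        action = moa.get((row["compound_id"], row["target_id"]), "unknown")
        direction = target_direction.get(row["target_id"])
        if action == "unknown" or direction is None:
            return False
        return (action in ACTIONS_UP and direction == "up") or (
            action in ACTIONS_DOWN and direction == "down"
        )

    out = records[~records.apply(conflict, axis=1)] if len(records) else records
    return out, _report("moa", records, out)


def stage_prioritize(
    records: pd.DataFrame, target_info: pd.DataFrame
) -> pd.DataFrame:
    """Rank surviving targets: early < moderate < advanced, then pChEMBL.

    ``target_info`` carries gene, stage, direction.  Within a priority
    tier, targets sort by maximum pChEMBL descending, then target id.
    """
    info = target_info.set_index("gene")
    rows = []
    for tgt, sub in records.groupby("target_id"):
        if tgt not in info.index:
            raise CascadeError(f"target {tgt!r} has no stage annotation")
        stage = info.loc[tgt, "stage"]
        if stage not in STAGE_PRIORITY:
            raise CascadeError(f"target {tgt!r} has unknown stage {stage!r}")
        best = sub.groupby("compound_id")["pchembl"].max().sort_values(ascending=False)
        rows.append(
            {
                "target": tgt,
                "stage": stage,
                "direction": info.loc[tgt, "direction"],
                "priority": STAGE_PRIORITY[stage],
                "max_pchembl": float(best.iloc[0]),
                "n_compounds": int(best.size),
                "compounds": ";".join(f"{c}({v:.2f})" for c, v in best.items()),
            }
        )
    final = pd.DataFrame(
        rows,
        columns=["target", "stage", "direction", "priority", "max_pchembl", "n_compounds", "compounds"],
    )
    if final.empty:
        return final
    return final.sort_values(
        by=["priority", "max_pchembl", "target"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)


def pchembl_from_concentration(concentration_um: float) -> float:
    """pChEMBL value of a micromolar activity concentration.

    pChEMBL = -log10(molar concentration); 100 uM -> 4.0, 1 nM -> 9.0.
    """
    if not (concentration_um > 0):
        raise CascadeError(f"concentration must be positive, got {concentration_um}")
    return -math.log10(concentration_um * 1e-6)


def concentration_from_pchembl(pchembl: float) -> float:
    """Inverse transform: micromolar concentration of a pChEMBL value."""
    return 10.0 ** (-pchembl) * 1e6


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_cascade(
    records: pd.DataFrame,
    compounds: pd.DataFrame,
    mouse_progression: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    normalized_mouse_genes: set,
    min_measurements: int = 30,
    min_phase: int = 2,
    excluded_prefixes: tuple[str, ...] = ("L01",),
    apply_moa: bool = True,
) -> CascadeResult:
    """Run the eight cascade steps in order with per-step provenance.

    ``mouse_progression`` is the stage gene table (gene, stage, direction)
    in mouse identifiers; ``normalized_mouse_genes`` the treatment-
    normalized subset.  Setting ``excluded_prefixes=()`` disables the ATC
    step; ``apply_moa=False`` disables the mode-of-action step.
    """
    records = validate_records(records).sort_values(RECORD_COLUMNS, kind="mergesort").reset_index(drop=True)
    steps: list[StepReport] = []

    rec, rep = quality_filter(records, min_measurements=min_measurements)
    steps.append(rep)

    human, olog = map_orthologs(mouse_progression, ortholog_map)
    human_prog = set(human["gene"])
    norm_human = set(human.loc[human["mouse_gene"].isin(set(normalized_mouse_genes)), "gene"])
    # mapping does not touch the bioactivity records; counts carry over
    steps.append(StepReport("orthologs", steps[-1].n_targets, steps[-1].n_compounds))

    rec, rep = intersect_targets(rec, human_prog)
    steps.append(rep)

    rec, rep = phase_filter(rec, compounds, min_phase=min_phase)
    steps.append(rep)

    rec, rep = normalized_target_filter(rec, norm_human)
    steps.append(rep)

    if excluded_prefixes:
        rec, rep = atc_filter(rec, compounds, excluded_prefixes=excluded_prefixes)
        steps.append(rep)

    if apply_moa:
        direction = human.set_index("gene")["direction"].to_dict()
        rec, rep = moa_filter(rec, compounds, direction)
        steps.append(rep)

    final = stage_prioritize(rec, human) if len(rec) else pd.DataFrame(
        columns=["target", "stage", "direction", "priority", "max_pchembl", "n_compounds", "compounds"]
    )
    return CascadeResult(steps=steps, final=final, records=rec.reset_index(drop=True), ortholog_log=olog)


# ---------------------------------------------------------------------------
# target categorization
# ---------------------------------------------------------------------------


def load_gene_families() -> dict[str, str]:
    """Bundled gene -> functional family map (MSigDB-style families)."""
    from importlib import resources

    path = resources.files("pkdrx").joinpath("data/gene_families.tsv")
    fam = {}
    with path.open() as fh:
        header = fh.readline()
        for line in fh:
            gene, family = line.rstrip("\n").split("\t")
            fam[gene] = family
    return fam


def load_prioritized_target_panel() -> list[str]:
    """Bundled panel of published prioritized ADPKD repurposing targets."""
    from importlib import resources

    path = resources.files("pkdrx").joinpath("data/adpkd_prioritized_targets.tsv")
    with path.open() as fh:
        fh.readline()
        return [line.strip() for line in fh if line.strip()]


def categorize_targets(genes, families: dict[str, str] | None = None) -> pd.Series:
    """Count genes per functional family; unannotated genes fall to 'Other'."""
    if families is None:
        families = load_gene_families()
    cats = pd.Series({g: families.get(g, "Other") for g in genes})
    return cats.value_counts()
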