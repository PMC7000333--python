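"""Synthetic cohort, treatment-arm and bioactivity-database generator.

Emulates the study design the pipeline was built for, with known ground
truth: a tamoxifen-inducible Pkd1-knockout mouse cohort harvested at five
weeks-post-induction timepoints (wild-type controls plus very early 2/3/6
wk, moderate 11-12 wk and advanced 15 wk disease), negative-binomial bulk
RNA-seq counts with planted stage-specific dysregulation archetypes, drug
treatment arms that move a known subset of the planted genes back toward
the wild-type level, a monotone two-kidney-weight/body-weight (2KW/BW)
phenotype, and a ChEMBL-style bioactivity table in which the survivors of
every prioritization-cascade step are planted by construction.

Two noise regimes:

* ``dispersion > 0`` — gamma-Poisson (negative binomial) counts with
  log-normal per-gene baselines; the regime used for power/recovery tests.
* ``dispersion == 0`` — deterministic counts ``round(mu * 2**jitter)``
  with a fixed zero-mean alternating jitter pattern, giving every gene an
  identical within-group variance and exactly-zero null log-fold-changes.
  This "exact" regime lets end-to-end runs reproduce the planted ground
  truth exactly.

Aberrant-cluster archetypes deserve a note: a gene whose only signal is a
single-sample spike can never pass a t-based FDR gate (the spike inflates
the very variance the mean shift is tested against), so planted aberrant
genes carry a genuine one-group signal — which is what makes them
differentially expressed — plus a much larger spike in one sample of a
different group that dominates their cluster's mean profile and triggers
the leave-one-sample-out aberrance flag downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Archetype:
    """A planted expression pattern: direction and per-week log2FC weights."""

    name: str
    stage: str                 # early | moderate | advanced
    direction: str             # up | down
    weights: dict              # week -> weight in (0, 1]


@dataclass(frozen=True)
class AberrantArchetype:
    """A planted single-sample artifact rider on a genuine one-group signal."""

    name: str
    carrier_week: float        # group carrying the genuine signal
    carrier_direction: str
    spike_week: float          # group containing the spiked sample
    spike_sample: int          # index of the spiked sample within its group
    spike_scale: float = 2.5   # spike log2FC = scale * effect * group size


@dataclass(frozen=True)
class TreatmentArm:
    name: str
    normalized_fraction: float = 1.0
    n_treated: int = 4
    n_genes: int = 40          # planted normalized genes for this arm
    genes: tuple = ()          # explicit gene set (overrides n_genes)


def default_archetypes() -> list[Archetype]:
    """The 12 retained patterns: 5 early, 4 moderate, 3 advanced."""
    return [
        Archetype("E1", "early", "up", {2: 1.0, 3: 1.0, 6: 1.0}),
        Archetype("E2", "early", "up", {2: 1.0, 3: 0.7, 6: 0.4, 12: 0.3}),
        Archetype("E3", "early", "up", {2: 0.3, 3: 0.8, 6: 1.0, 12: 0.4}),
        Archetype("E4", "early", "down", {2: 1.0, 3: 1.0, 6: 0.8, 12: 0.3}),
        Archetype("E5", "early", "down", {2: 0.4, 3: 1.0, 6: 0.9}),
        Archetype("M1", "moderate", "up", {6: 0.3, 12: 1.0, 15: 0.7}),
        Archetype("M2", "moderate", "up", {12: 1.0, 15: 0.9}),
        Archetype("M3", "moderate", "down", {6: 0.2, 12: 1.0, 15: 0.8}),
        Archetype("M4", "moderate", "down", {12: 1.0, 15: 0.6}),
        Archetype("A1", "advanced", "up", {12: 0.4, 15: 1.0}),
        Archetype("A2", "advanced", "down", {12: 0.5, 15: 1.0}),
        Archetype("A3", "advanced", "down", {15: 1.0}),
    ]


def default_aberrant() -> list[AberrantArchetype]:
    return [
        AberrantArchetype("AB1", carrier_week=2, carrier_direction="up", spike_week=15, spike_sample=0),
        AberrantArchetype("AB2", carrier_week=6, carrier_direction="down", spike_week=2, spike_sample=2),
        AberrantArchetype("AB3", carrier_week=12, carrier_direction="up", spike_week=6, spike_sample=1),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort."""

    seed: int
    n_genes: int = 2000
    n_cluster_genes_per_archetype: int = 25
    n_genes_per_aberrant: int = 10
    archetypes: tuple = field(default_factory=lambda: tuple(default_archetypes()))
    aberrant: tuple = field(default_factory=lambda: tuple(default_aberrant()))
    # samples per group: WT controls + five mutant harvests
    group_sizes: dict = field(
        default_factory=lambda: {"WT": 5, "wk2": 4, "wk3": 4, "wk6": 4, "wk12": 5, "wk15": 3}
    )
    group_weeks: dict = field(
        default_factory=lambda: {"WT": 0.0, "wk2": 2.0, "wk3": 3.0, "wk6": 6.0, "wk12": 12.0, "wk15": 15.0}
    )
    effect_size: float = 2.0            # log2FC of planted genes at weight 1
    dispersion: float = 0.1             # NB dispersion; 0 = exact regime
    # median baseline of 2^9 = 512 counts/gene: a ~2M-read library over the
    # scaled-down 2000 genes gives the same per-gene depth as ~30M reads over
    # 20k genes, so the NB dispersion (not shot noise) dominates as in real
    # deep bulk RNA-seq
    mean_expression_log2: float = 9.0
    sd_expression_log2: float = 1.5
    depth_sd: float = 0.15              # log-normal library depth spread
    exact_jitter: float = 0.05          # log2 jitter sd in the exact regime
    treatment_arms: tuple = field(
        default_factory=lambda: (
            TreatmentArm("curcumin"),
            TreatmentArm("rapamycin"),
            TreatmentArm("sActRIIB-Fc"),
        )
    )
    comparator_group: str = "wk12"      # matched untreated harvest for arms
    min_comparator_weight: float = 0.5  # eligibility for planted normalization
    # 2KW/BW (%) means per group, strictly increasing over mutant stages
    kwbw_means: dict = field(
        default_factory=lambda: {"WT": 1.2, "wk2": 1.5, "wk3": 1.9, "wk6": 2.6, "wk12": 5.5, "wk15": 9.0}
    )
    kwbw_sd_frac: float = 0.08

    def validate(self) -> "SimulationConfig":
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise SimulationError(f"group {g} has size {n} < 2")
        for arm in self.treatment_arms:
            if not (0.0 <= arm.normalized_fraction <= 1.0):
                raise SimulationError(f"arm {arm.name}: normalized_fraction outside [0, 1]")
            if arm.n_treated < 2:
                raise SimulationError(f"arm {arm.name}: needs >= 2 treated samples")
        mutant = [g for g in self.group_sizes if g != "WT"]
        mutant.sort(key=lambda g: self.group_weeks[g])
        means = [self.kwbw_means[g] for g in mutant]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise SimulationError("kwbw means must be strictly increasing over mutant stages")
        n_planted = len(self.archetypes) * self.n_cluster_genes_per_archetype + len(
            self.aberrant
        ) * self.n_genes_per_aberrant
        if n_planted > self.n_genes:
            raise SimulationError("more planted genes than total genes")
        return self

    @property
    def exact(self) -> bool:
        return self.dispersion == 0


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests.

    ``progression`` holds mouse gene, stage, direction, archetype for the
    non-aberrant planted genes; ``cascade_survivors`` (filled by the
    bioactivity generator) maps each cascade step name to its expected
    surviving target and compound sets, nested by construction.
    """

    progression: pd.DataFrame
    aberrant: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "archetype", "carrier_week", "carrier_direction"]
        )
    )
    normalized_by_arm: dict = field(default_factory=dict)
    cascade_survivors: dict = field(default_factory=dict)

    @property
    def aberrant_genes(self) -> list:
        return sorted(self.aberrant["gene"])

    @property
    def progression_genes(self) -> set:
        return set(self.progression["gene"])

    @property
    def normalized_genes(self) -> set:
        out: set = set()
        for genes in self.normalized_by_arm.values():
            out |= set(genes)
        return out

    def stage_of(self) -> dict:
        return dict(zip(self.progression["gene"], self.progression["stage"]))

    def direction_of(self) -> dict:
        return dict(zip(self.progression["gene"], self.progression["direction"]))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _jitter_pattern(n: int) -> np.ndarray:
    """Zero-mean +/-1 alternating pattern of length n (last entry 0 if odd)."""
    pat = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(n)])
    if n % 2 == 1:
        pat[-1] = 0.0
    return pat


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.round(mu).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def mouse_gene_ids(n: int) -> list[str]:
    return [f"Pkdg{i:04d}" for i in range(1, n + 1)]


def human_symbol(mouse_id: str) -> str:
    return mouse_id.upper()


# ---------------------------------------------------------------------------
# progression cohort
# ---------------------------------------------------------------------------


def simulate_progression_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the untreated cohort: counts, sample metadata, ground truth.

    Counts are genes x samples; metadata has one row per sample with group,
    weeks_post_induction, kw_bw, treatment ("none") and sex.  Planted genes
    deviate from the wild-type baseline only at their archetype's weeks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = mouse_gene_ids(config.n_genes)

    # assign planted genes from a seeded permutation
    perm = rng.permutation(config.n_genes)
    cursor = 0
    gene_archetype: dict[str, Archetype] = {}
    for arch in config.archetypes:
        for i in perm[cursor : cursor + config.n_cluster_genes_per_archetype]:
            gene_archetype[genes[i]] = arch
        cursor += config.n_cluster_genes_per_archetype
    gene_aberrant: dict[str, AberrantArchetype] = {}
    for ab in config.aberrant:
        for i in perm[cursor : cursor + config.n_genes_per_aberrant]:
            gene_aberrant[genes[i]] = ab
        cursor += config.n_genes_per_aberrant

    base = 2.0 ** rng.normal(config.mean_expression_log2, config.sd_expression_log2, config.n_genes)
    base = pd.Series(base, index=genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # per-gene per-group log2 signal
    weeks = config.group_weeks
    groups = list(config.group_sizes)
    signal = pd.DataFrame(0.0, index=genes, columns=groups)
    for g, arch in gene_archetype.items():
        d = 1.0 if arch.direction == "up" else -1.0
        for grp in groups:
            w = arch.weights.get(weeks[grp], arch.weights.get(int(weeks[grp]), 0.0))
            if w:
                signal.loc[g, grp] = d * w * config.effect_size
    for g, ab in gene_aberrant.items():
        d = 1.0 if ab.carrier_direction == "up" else -1.0
        carrier_grp = next(grp for grp in groups if weeks[grp] == ab.carrier_week)
        signal.loc[g, carrier_grp] = d * config.effect_size

    counts = {}
    meta = []
    for grp in groups:
        n = config.group_sizes[grp]
        pat = _jitter_pattern(n)
        spike_grp = {
            ab: weeks[grp] == ab.spike_week for ab in config.aberrant
        }
        for j in range(n):
            sid = f"{grp}_{j + 1}"
            log2sig = signal[grp].to_numpy().copy()
            if config.exact:
                # gene-and-sample alternating jitter: zero within-group mean,
                # identical within-group variance for every gene
                gene_phase = np.where(np.arange(config.n_genes) % 2 == 0, 1.0, -1.0)
                log2sig = log2sig + config.exact_jitter * pat[j] * gene_phase
                depth = 1.0
            else:
                depth = float(np.exp(rng.normal(0.0, config.depth_sd)))
            for ab, here in spike_grp.items():
                if here and j == ab.spike_sample:
                    spike = ab.spike_scale * config.effect_size * n
                    for g2, ab2 in gene_aberrant.items():
                        if ab2 is ab:
                            log2sig[gene_pos[g2]] += spike
            mu = base.to_numpy() * (2.0 ** log2sig) * depth
            counts[sid] = _draw_counts(rng, mu, config.dispersion)
            kw_mean = config.kwbw_means[grp]
            if config.exact:
                kw = kw_mean * (1.0 + 0.02 * pat[j])
            else:
                kw = float(kw_mean * np.exp(rng.normal(0.0, config.kwbw_sd_frac)))
            meta.append(
                {
                    "sample_id": sid,
                    "group": grp,
                    "weeks_post_induction": weeks[grp],
                    "kw_bw": kw,
                    "treatment": "none",
                    "sex": "M",
                }
            )

    counts_df = pd.DataFrame(counts, index=genes)
    info_df = pd.DataFrame(meta)
    prog = pd.DataFrame(
        [
            {"gene": g, "stage": a.stage, "direction": a.direction, "archetype": a.name}
            for g, a in sorted(gene_archetype.items())
        ],
        columns=["gene", "stage", "direction", "archetype"],
    )
    aber = pd.DataFrame(
        [
            {
                "gene": g,
                "archetype": ab.name,
                "carrier_week": ab.carrier_week,
                "carrier_direction": ab.carrier_direction,
            }
            for g, ab in sorted(gene_aberrant.items())
        ],
        columns=["gene", "archetype", "carrier_week", "carrier_direction"],
    )
    truth = GroundTruth(progression=prog, aberrant=aber)
    return counts_df, info_df, truth


# ---------------------------------------------------------------------------
# treatment arms
# ---------------------------------------------------------------------------


def eligible_normalization_genes(config: SimulationConfig, truth: GroundTruth) -> list[str]:
    """Planted genes dysregulated strongly enough at the arm comparator week.

    A treatment harvested at the comparator week can only visibly reverse
    genes whose archetype weight at that week is at least
    ``min_comparator_weight``; flat genes have nothing to normalize there.
    """
    week = config.group_weeks[config.comparator_group]
    by_name = {a.name: a for a in config.archetypes}
    out = []
    for _, row in truth.progression.iterrows():
        w = by_name[row["archetype"]].weights.get(week, by_name[row["archetype"]].weights.get(int(week), 0.0))
        if w >= config.min_comparator_weight:
            out.append(row["gene"])
    return out


def simulate_treatment_arms(
    base_counts: pd.DataFrame,
    base_info: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Append treated samples for each arm; record which genes each arm fixes.

    Treated samples are drawn at the comparator group's means with each
    arm's planted-normalized genes moved back toward wild type by the arm's
    ``normalized_fraction``.  Arms draw disjoint gene sets from the
    eligible pool unless explicit gene lists are supplied.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = list(base_counts.index)
    gene_pos = {g: i for i, g in enumerate(genes)}

    eligible = eligible_normalization_genes(config, truth)
    pool = list(rng.permutation(eligible))
    normalized_by_arm: dict[str, set] = {}
    for arm in config.treatment_arms:
        if arm.genes:
            unknown = [g for g in arm.genes if g not in gene_pos]
            if unknown:
                raise SimulationError(f"arm {arm.name} references unknown genes: {unknown[:5]}")
            chosen = list(arm.genes)
        else:
            if len(pool) < arm.n_genes:
                raise SimulationError(
                    f"not enough eligible genes left for arm {arm.name} "
                    f"({len(pool)} < {arm.n_genes})"
                )
            chosen, pool = pool[: arm.n_genes], pool[arm.n_genes :]
        normalized_by_arm[arm.name] = set(chosen)

    # comparator-group mean signal, reconstructed from the planted design
    week = config.group_weeks[config.comparator_group]
    by_name = {a.name: a for a in config.archetypes}
    sig_comp = np.zeros(len(genes))
    for _, row in truth.progression.iterrows():
        arch = by_name[row["archetype"]]
        w = arch.weights.get(week, arch.weights.get(int(week), 0.0))
        if w:
            d = 1.0 if row["direction"] == "up" else -1.0
            sig_comp[gene_pos[row["gene"]]] = d * w * config.effect_size
    for _, row in truth.aberrant.iterrows():
        if row["carrier_week"] == week:
            d = 1.0 if row["carrier_direction"] == "up" else -1.0
            sig_comp[gene_pos[row["gene"]]] = d * config.effect_size

    base_mu = _baseline_means(config)
    counts = {}
    meta = []
    for arm in config.treatment_arms:
        pat = _jitter_pattern(arm.n_treated)
        norm_mask = np.zeros(len(genes))
        for g in normalized_by_arm[arm.name]:
            norm_mask[gene_pos[g]] = 1.0
        log2_treated = sig_comp * (1.0 - arm.normalized_fraction * norm_mask)
        for j in range(arm.n_treated):
            sid = f"{arm.name}_{j + 1}"
            sig = log2_treated.copy()
            if config.exact:
                gene_phase = np.where(np.arange(len(genes)) % 2 == 0, 1.0, -1.0)
                sig = sig + config.exact_jitter * pat[j] * gene_phase
                depth = 1.0
            else:
                depth = float(np.exp(rng.normal(0.0, config.depth_sd)))
            mu = base_mu * (2.0 ** sig) * depth
            counts[sid] = _draw_counts(rng, mu, config.dispersion)
            kw_mean = config.kwbw_means[config.comparator_group] * 0.7  # partial rescue
            kw = kw_mean if config.exact else float(kw_mean * np.exp(rng.normal(0.0, config.kwbw_sd_frac)))
            meta.append(
                {
                    "sample_id": sid,
                    "group": config.comparator_group,
                    "weeks_post_induction": week,
                    "kw_bw": kw,
                    "treatment": arm.name,
                    "sex": "M",
                }
            )

    treated_df = pd.DataFrame(counts, index=base_counts.index)
    all_counts = pd.concat([base_counts, treated_df], axis=1)
    all_info = pd.concat([base_info, pd.DataFrame(meta)], ignore_index=True)
    new_truth = GroundTruth(
        progression=truth.progression,
        aberrant=truth.aberrant,
        normalized_by_arm=normalized_by_arm,
        cascade_survivors=truth.cascade_survivors,
    )
    return all_counts, all_info, new_truth


def _baseline_means(config: SimulationConfig) -> np.ndarray:
    """Re-derive the per-gene baseline means from the seed (shared with
    simulate_progression_counts, which draws them first)."""
    rng = np.random.default_rng(config.seed)
    rng.permutation(config.n_genes)  # consume the planted-gene permutation
    return 2.0 ** rng.normal(config.mean_expression_log2, config.sd_expression_log2, config.n_genes)


def simulate_cohort(config: SimulationConfig):
    """Progression cohort plus treatment arms in one call."""
    counts, info, truth = simulate_progression_counts(config)
    return simulate_treatment_arms(counts, info, truth, config)


# ---------------------------------------------------------------------------
# bioactivity database
# ---------------------------------------------------------------------------

# record-filter order of the prioritization cascade; a planted item's
# fail_step is the EARLIEST step at which its attributes disqualify it
_STEP_INDEX = {"quality": 1, "intersect": 2, "phase": 3, "normalized": 4, "atc": 5, "moa": 6}
_SURVIVE = 99


@dataclass(frozen=True)
class TargetPlan:
    symbol: str                # human gene symbol
    fail_step: str | None      # None = survives to the final table
    stage: str | None = None
    direction: str | None = None


def _standalone_truth(rng: np.random.Generator) -> GroundTruth:
    """Minimal progression/normalized truth for standalone database use."""
    stages = ["early", "moderate", "advanced"]
    rows = []
    for i in range(60):
        rows.append(
            {
                "gene": f"Pkdg{9000 + i}",
                "stage": stages[i % 3],
                "direction": "up" if i % 2 == 0 else "down",
                "archetype": "S",
            }
        )
    prog = pd.DataFrame(rows)
    normalized = set(prog["gene"].iloc[:30])
    return GroundTruth(progression=prog, normalized_by_arm={"synthetic-arm": normalized})


def simulate_bioactivity_db(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    compounds_per_target: int = 8,
    assays_per_compound: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """ChEMBL-style bioactivity export with planted cascade survivors.

    Returns (bioactivity records, compound annotations, ortholog map,
    updated ground truth).  Every prioritization-cascade step has planted
    items that fail exactly there: low-confidence assays, absent pChEMBL,
    non-human targets, under-measured targets (<30 records), non-progression
    targets, compounds never past clinical phase 1, non-normalized targets,
    antineoplastic (L01) compounds and conflicting modes of action.  The
    expected survivor sets of each step are derived from the construction
    plan — not by running the filters — and stored in
    ``truth.cascade_survivors``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    if truth is None:
        truth = _standalone_truth(rng)
    if not truth.normalized_by_arm:
        raise SimulationError("ground truth has no normalized genes; simulate treatment arms first")

    prog = truth.progression
    normalized = truth.normalized_genes
    # mouse genes reserved for ortholog-mapping edge cases: progression genes
    # that are neither normalized nor usable as planted targets
    spare = sorted(set(prog["gene"]) - normalized)
    unmapped_mouse = spare[:2]
    multimapped_mouse = spare[2:4]
    usable_norm = sorted(normalized)
    usable_nonnorm = spare[4:]

    def take_norm(n: int, stage: str | None = None) -> list[str]:
        nonlocal usable_norm
        if stage is not None:
            sub = prog.set_index("gene").loc[usable_norm]
            pick = [g for g in usable_norm if sub.loc[g, "stage"] == stage][:n]
        else:
            pick = usable_norm[:n]
        if len(pick) < n:
            raise SimulationError("not enough normalized genes to plant the cascade fixture")
        usable_norm = [g for g in usable_norm if g not in pick]
        return pick

    stage_of = truth.stage_of()
    direction_of = truth.direction_of()

    plans: list[TargetPlan] = []
    # quality failures (never reach the progression intersect)
    plans += [
        TargetPlan("DECOYC8", "quality"),    # confidence 8
        TargetPlan("DECOYNP", "quality"),    # no pChEMBL
        TargetPlan("DECOYRAT", "quality"),   # non-human target
        TargetPlan("DECOYFEW", "quality"),   # < 30 measurements
    ]
    plans += [TargetPlan(f"DECOYX{i}", "intersect") for i in range(3)]
    for g in take_norm(2):
        plans.append(TargetPlan(human_symbol(g), "phase", stage_of[g], direction_of[g]))
    for g in usable_nonnorm[:2]:
        plans.append(TargetPlan(human_symbol(g), "normalized", stage_of[g], direction_of[g]))
    for g in take_norm(2):
        plans.append(TargetPlan(human_symbol(g), "atc", stage_of[g], direction_of[g]))
    moa_gene = next(
        g for g in list(usable_norm) if direction_of[g] == "up"
    )
    usable_norm.remove(moa_gene)
    plans.append(TargetPlan(human_symbol(moa_gene), "moa", stage_of[moa_gene], direction_of[moa_gene]))
    for g in take_norm(3, stage="moderate") + take_norm(3, stage="advanced"):
        plans.append(TargetPlan(human_symbol(g), None, stage_of[g], direction_of[g]))

    records: list[dict] = []
    fail_idx: list[int] = []
    compound_rows: list[dict] = []
    cpd_counter = [0]
    assay_counter = [0]

    def new_compound(max_phase: int, atc: list[str], moa: list[tuple]) -> str:
        cpd_counter[0] += 1
        cid = f"CPD{cpd_counter[0]:04d}"
        compound_rows.append(
            {
                "compound_id": cid,
                "name": f"compound-{cpd_counter[0]}",
                "max_phase": max_phase,
                "atc_codes": atc,
                "moa": moa,
            }
        )
        return cid

    def add_records(
        target: str, cid: str, n: int, step: str | None,
        confidence: int = 9, pchembl_absent: bool = False, organism: str = "Homo sapiens",
    ) -> None:
        idx = _SURVIVE if step is None else _STEP_INDEX[step]
        for _ in range(n):
            assay_counter[0] += 1
            records.append(
                {
                    "compound_id": cid,
                    "target_id": target,
                    "target_organism": organism,
                    "pchembl": (np.nan if pchembl_absent else round(float(rng.uniform(4.5, 9.0)), 2)),
                    "confidence_score": confidence,
                    "assay_id": f"A{assay_counter[0]:06d}",
                }
            )
            fail_idx.append(idx)

    benign_atc_pool = ["M01AG", "C07AB", "N02BA01", "A10BB", ""]
    for plan in plans:
        n_cpds = compounds_per_target
        per_cpd = assays_per_compound
        if plan.fail_step == "quality" and plan.symbol == "DECOYFEW":
            n_cpds, per_cpd = 5, 2  # only 10 qualifying measurements
        for c in range(n_cpds):
            atc = [a for a in [benign_atc_pool[c % len(benign_atc_pool)]] if a]
            if plan.fail_step == "phase":
                cid = new_compound(max_phase=int(rng.integers(0, 2)), atc=atc, moa=[])
            elif plan.fail_step == "atc":
                cid = new_compound(max_phase=int(rng.integers(2, 5)), atc=["L01XA01" if c % 2 else "L01AA01"], moa=[])
            elif plan.fail_step == "moa":
                cid = new_compound(max_phase=int(rng.integers(2, 5)), atc=atc, moa=[(plan.symbol, "agonist")])
            else:
                moa = []
                if plan.fail_step is None and c == 0 and plan.direction is not None:
                    # a survivor with an explicitly corrective mode of action
                    moa = [(plan.symbol, "inhibitor" if plan.direction == "up" else "agonist")]
                cid = new_compound(max_phase=int(rng.integers(2, 5)), atc=atc, moa=moa)
            add_records(
                plan.symbol,
                cid,
                per_cpd,
                plan.fail_step,
                confidence=8 if plan.symbol == "DECOYC8" else 9,
                pchembl_absent=plan.symbol == "DECOYNP",
                organism="Rattus norvegicus" if plan.symbol == "DECOYRAT" else "Homo sapiens",
            )

    # compound-level removals on a surviving target: the target persists while
    # individual compounds drop at phase / atc / moa
    survivor = next(p for p in plans if p.fail_step is None)
    cid = new_compound(max_phase=1, atc=[], moa=[])
    add_records(survivor.symbol, cid, assays_per_compound, "phase")
    cid = new_compound(max_phase=4, atc=["L01XE01"], moa=[])
    add_records(survivor.symbol, cid, assays_per_compound, "atc")
    conflict_action = "agonist" if survivor.direction == "up" else "inhibitor"
    cid = new_compound(max_phase=4, atc=[], moa=[(survivor.symbol, conflict_action)])
    add_records(survivor.symbol, cid, assays_per_compound, "moa")

    records_df = pd.DataFrame(records)
    compounds_df = pd.DataFrame(compound_rows)

    # ortholog map: all planted mouse genes map Title-case -> UPPER-case,
    # with two genes left unmapped and two mapped to a second human symbol
    mouse_ids = sorted(set(prog["gene"]) | set(truth.aberrant_genes))
    pairs = [
        {"mouse_id": m, "human_symbol": human_symbol(m)}
        for m in mouse_ids
        if m not in unmapped_mouse
    ]
    for m in multimapped_mouse:
        pairs.append({"mouse_id": m, "human_symbol": human_symbol(m) + "B"})
    ortholog_df = pd.DataFrame(pairs, columns=["mouse_id", "human_symbol"])

    # survivor sets per step, from the construction plan
    fail = np.asarray(fail_idx)
    survivors: dict[str, dict] = {}
    for step, k in _STEP_INDEX.items():
        alive = records_df[fail > k]
        survivors[step] = {
            "targets": set(alive["target_id"]),
            "compounds": set(alive["compound_id"]),
        }
        if step == "quality":
            survivors["orthologs"] = dict(survivors["quality"])
    survivors["final"] = dict(survivors["moa"])

    new_truth = GroundTruth(
        progression=truth.progression,
        aberrant=truth.aberrant,
        normalized_by_arm=truth.normalized_by_arm,
        cascade_survivors=survivors,
    )
    return records_df, compounds_df, ortholog_df, new_truth
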