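"""End-to-end orchestration: counts -> stage genes -> candidates.

``run_pipeline`` executes the full analysis on either synthetic inputs
(generated from a :class:`~pkdrx.simulate.SimulationConfig`) or tables
loaded from disk, writes every intermediate table plus a JSON run report
with per-stage counts, and fails fast with the stage name on any error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import cascade as casc
from . import clusters as clu
from . import expression as expr
from . import io as pio
from . import simulate as sim
from . import stagestats
from . import treatment as trt

log = logging.getLogger("pkdrx")


@dataclass
class RunConfig:
    """Every threshold the pipeline applies, in one place.

    Defaults are the analysis defaults: progression DEGs at FDR < 0.005,
    treatment DEGs at raw p < 0.05, noise filter cpm < 2 in more than half
    the samples, 15 clusters, clinical phase >= 2, >= 30 measurements per
    target, antineoplastic ATC prefix L01 excluded.
    """

    seed: int = 0
    out_dir: str | None = None
    fdr_progression: float = 0.005
    p_treatment: float = 0.05
    cpm_threshold: float = 2.0
    noise_fraction: float = 0.5
    k_clusters: int = 15
    dominance: float = 0.5
    min_phase: int = 2
    min_measurements: int = 30
    atc_excluded: tuple = ("L01",)
    stage_windows: dict = field(default_factory=lambda: dict(clu.DEFAULT_STAGE_WINDOWS))
    sim: sim.SimulationConfig | None = None
    # optional input paths; when set they override simulation
    counts_path: str | None = None
    metadata_path: str | None = None
    bioactivities_path: str | None = None
    compounds_path: str | None = None
    orthologs_path: str | None = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run expression -> clusters -> stage stats -> treatment -> cascade.

    Returns the run report (also written to ``out_dir`` when set, together
    with all intermediate tables).
    """
    report: dict = {"seed": config.seed, "config": _config_echo(config)}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    counts, info, truth, bio, cpds, orthologs = _load_inputs(config)
    report["n_genes"] = int(counts.shape[0])
    report["n_samples"] = int(counts.shape[1])

    em, kept = _normalize(counts, config)
    report["n_genes_after_noise_filter"] = int(len(kept))
    em_kept = expr.ExpressionMatrix(logcpm=em.logcpm.loc[kept], lib_size=em.lib_size, tmm=em.tmm)

    union, de_tables = _progression_degs(em_kept, info, config)
    report["n_progression_degs"] = len(union)

    assignment, groups = _cluster_stage(em_kept, info, union, config)
    report["clusters"] = {
        "k": config.k_clusters,
        "retained": assignment.retained(),
        "aberrant": sorted(c for c, f in assignment.qc_flag.items() if f == "aberrant"),
        "sizes": {int(c): int(n) for c, n in assignment.sizes.items()},
    }
    report["stage_group_sizes"] = {s: len(g) for s, g in groups.genes.items()}

    pca_res = _pca(em_kept, info)
    report["pca_variance_fractions"] = [round(float(v), 4) for v in pca_res.variance_fraction[:3]]

    rho = stagestats.spearman_kwbw(em_kept.logcpm, assignment, info)
    report["spearman_kwbw_by_cluster"] = {int(c): round(float(v), 3) for c, v in rho.items()}

    arms, normalized = _treatment(em_kept, info, groups, config)
    report["treatment_arms"] = {
        a.name: {"n_significant": a.n_significant, "balanced_size": a.balanced_size} for a in arms
    }
    report["balanced_size"] = arms[0].balanced_size if arms else None
    report["n_normalized_genes"] = len(normalized.genes)

    result = _cascade(bio, cpds, groups, normalized, orthologs, config)
    report["cascade"] = [s.to_dict() for s in result.steps]
    report["n_final_targets"] = int(result.final.shape[0])
    report["final_targets"] = list(result.final["target"])

    if out:
        pio.write_counts_tsv(counts, out / "counts.tsv")
        pio.write_metadata_tsv(info, out / "samples.tsv")
        pio.write_stage_genes_tsv(groups.as_frame(), out / "stage_genes.tsv")
        normalized.table.to_csv(out / "normalized_genes.tsv", sep="\t", index=False)
        result.final.to_csv(out / "candidates.tsv", sep="\t", index=False)
        pio.write_json(report, out / "run_report.json")
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("sim",) and not k.endswith("_path")
    }
    echo["atc_excluded"] = list(config.atc_excluded)
    echo["stage_windows"] = {k: list(v) for k, v in config.stage_windows.items()}
    if config.sim is not None:
        echo["sim_seed"] = config.sim.seed
        echo["sim_dispersion"] = config.sim.dispersion
        echo["sim_effect_size"] = config.sim.effect_size
    return echo


@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.counts_path:
        for name, p in (
            ("counts", config.counts_path),
            ("metadata", config.metadata_path),
            ("bioactivities", config.bioactivities_path),
            ("compounds", config.compounds_path),
            ("orthologs", config.orthologs_path),
        ):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing {name} input file: {p}")
        counts = pio.read_counts_tsv(config.counts_path)
        info = pio.read_metadata_tsv(config.metadata_path)
        bio = pio.read_bioactivities_csv(config.bioactivities_path)
        cpds = pio.read_compounds_csv(config.compounds_path)
        orthologs = pio.read_orthologs_tsv(config.orthologs_path)
        return counts, info, None, bio, cpds, orthologs
    sim_cfg = config.sim or sim.SimulationConfig(seed=config.seed)
    counts, info, truth = sim.simulate_cohort(sim_cfg)
    bio, cpds, orthologs, truth = sim.simulate_bioactivity_db(sim_cfg, truth)
    return counts, info, truth, bio, cpds, orthologs


@_stage("normalize")
def _normalize(counts, config):
    em = expr.normalize(counts)
    cpm = expr.compute_cpm(counts, tmm=em.tmm)
    kept = expr.noise_filter(cpm, threshold=config.cpm_threshold, fraction=config.noise_fraction)
    return em, kept


@_stage("progression_degs")
def _progression_degs(em, info, config):
    return clu.progression_deg_union(em, info, fdr_threshold=config.fdr_progression)


@_stage("clusters")
def _cluster_stage(em, info, union, config):
    if not union:
        raise clu.ClusterError("empty progression DEG union; nothing to cluster")
    profiles = clu.relative_profiles(em, info, genes=sorted(union))
    assignment = clu.hierarchical_cluster(profiles, k=config.k_clusters)
    assignment = clu.flag_aberrant_clusters(assignment, em, info, dominance=config.dominance)
    groups = clu.assign_stage(assignment, config.stage_windows)
    return assignment, groups


@_stage("pca")
def _pca(em, info):
    meta = info.set_index("sample_id")
    untreated = [s for s in em.logcpm.columns if meta.loc[s, "treatment"] == "none"]
    return expr.pca(em.logcpm[untreated])


@_stage("treatment")
def _treatment(em, info, groups, config):
    meta = info.set_index("sample_id")
    arm_names = sorted(set(meta["treatment"]) - {"none"})
    arms = []
    for name in arm_names:
        treated = list(meta.index[meta["treatment"] == name])
        comparator_groups = set(meta.loc[treated, "group"])
        untreated = list(
            meta.index[(meta["treatment"] == "none") & meta["group"].isin(comparator_groups)]
        )
        arms.append(trt.treatment_de(em, treated, untreated, name, p_threshold=config.p_treatment))
    if not arms:
        return [], trt.NormalizedGeneSet()
    arms = trt.balance_lists(arms)
    normalized = trt.normalized_genes(groups, arms)
    return arms, normalized


@_stage("cascade")
def _cascade(bio, cpds, groups, normalized, orthologs, config):
    return casc.run_cascade(
        bio,
        cpds,
        groups.as_frame(),
        orthologs,
        normalized.genes,
        min_measurements=config.min_measurements,
        min_phase=config.min_phase,
        excluded_prefixes=config.atc_excluded,
    )
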