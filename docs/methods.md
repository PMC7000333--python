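# Methods

This note documents the models, parameter choices and numerical decisions
behind `pkdrx`, in the order the pipeline runs.

## Study design being modeled

The pipeline targets a progressive-disease transcriptomics design: a
wild-type control group and five mutant groups of a conditional
*Pkd1*-knockout mouse, harvested 2, 3, 6, 11–12 and 15 weeks after gene
inactivation. The 2/3/6-week harvests represent very early (pre-cystic)
disease, 11–12 weeks moderate disease and 15 weeks advanced disease; the
combined two-kidney-weight to body-weight ratio (2KW/BW, reported here in
percent) increases monotonically over these stages and serves as the
severity phenotype. Default group sizes are 5 (WT), 4, 4, 4, 5, 3 animals.
Drug treatment arms (defaults named curcumin, rapamycin, sActRIIB-Fc) are
harvested alongside the moderate-stage group, which acts as their matched
untreated comparator.

## Normalization

Counts are scaled to counts-per-million on effective library sizes
`N_s * f_s`, where `f_s` is the TMM factor: the exponentiated
inverse-variance-weighted mean of per-gene log2 abundance ratios (M-values)
against a reference sample, after trimming the extreme 30 % of M-values and
5 % of A-values and excluding genes with a zero count in either sample.
The reference is the sample whose upper quartile of library-scaled counts is
closest to the mean upper quartile. Factors are rescaled to geometric mean
1, so they are relative corrections, not depth estimates. Genes with
cpm < 2 in strictly more than half the samples are removed; "strictly more
than" means a gene low in exactly half the samples is retained. The
retained genes define the background for all enrichment statistics.

## Differential expression

Pipelines of this kind conventionally call voom/limma. `pkdrx`
deliberately ships a self-contained equivalent rather than wrapping an
external engine: an ordinary two-group linear model per gene on
`log2(cpm + 0.5)` (the 0.5 pseudo-count avoids −∞ and is standard practice
for logged CPM), with the pooled residual variance shrunk toward an
across-gene prior,

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d),

and p-values from the t distribution at `d0 + d` degrees of freedom. The
prior (`d0`, `s0^2`) is fitted by method of moments to the marginal
scaled-F model of the gene variances; when the observed variance dispersion
is consistent with homogeneous variances the fit degenerates to complete
shrinkage (all genes share the mean variance, effectively normal tails).
Variances are floored at 1e-8 so zero-variance genes (possible in the
deterministic regime) cannot produce undefined statistics; a gene with
identical values in both groups still reports t = 0, p = 1 because its
log-fold-change is exactly zero. Precision weights are not reimplemented;
the consequence is somewhat less power for very low-count genes, which the
recovery tests quantify rather than hide.

Progression genes are the union over all pairwise group contrasts
(control included) of genes at Benjamini–Hochberg FDR < 0.005. BH is the
step-up procedure with enforced monotonicity, implemented directly and
cross-checked against statsmodels in the tests.

## Clustering and stage grouping

Gene profiles are the per-timepoint mean log2 ratio of each mutant group to
the control mean. Profiles are clustered with complete-linkage
agglomerative clustering on Euclidean distances and the tree is cut into
exactly 15 clusters. Genes are sorted lexicographically before clustering
so the partition is invariant to input order.

A cluster is flagged *aberrant* when its apparent signal lives in a single
sample: leaving out one mutant sample at a time, if the maximum absolute
profile value drops by more than 50 % (the `dominance` parameter) under
some single omission, the cluster is removed from stage grouping. The
50 % default is the value at which a cluster whose deviation sits entirely
in one sample flags while a cluster whose deviation is spread over a
4-animal group (each sample carrying ~25 % of the signal) does not.

Retained clusters are grouped automatically by peak position: the stage is
the window ({2,3,6} early, {11,12} moderate, {15} advanced weeks)
containing the timepoint of maximum |mean log2 ratio|, and the direction is
the sign at that peak. (Stage grouping of clusters is often done by visual
inspection; the peak-window rule is a reproducible automation of it.)

## Overlap and annotation statistics

The representation factor of two gene sets A, B in background N is
`RF = k / (|A||B|/N)` with k the observed overlap; RF = 1 is the
independence expectation. An exact hypergeometric tail probability
(P[overlap ≥ k]) is attached as an optional significance measure — the
statistic itself is the RF. Over-representation analysis is the one-sided
hypergeometric test of a gene set against GMT pathway collections
intersected with the expressed-gene background, reported at raw p < 0.05
with a BH column appended. Spearman correlations with 2KW/BW use mid-ranks
on ties and average gene-level coefficients within a cluster; constant
genes are skipped, a constant phenotype is an error.

## Treatment response

Each arm is compared to its own matched untreated harvest group (never
pooled controls) with the same moderated t, gated on raw p < 0.05.
Because arms differ widely in perturbation breadth, all significant lists
are truncated to the smallest arm's count before interpretation, keeping
each list's p-ascending prefix (ties at the cutoff broken by larger
|log2FC|, then gene id, so output is deterministic). A progression gene is
*normalized* iff at least one balanced list contains it with a
treated-vs-untreated log2FC opposing its progression direction. No
magnitude threshold is imposed: the verbal rule "not or less increased"
states a direction, not an effect size, and adding one would be an
undeclared extra parameter.

## Repurposing cascade

The eight steps run in a fixed order (quality → ortholog mapping →
progression intersect → clinical phase → normalized restriction → ATC →
mode of action → stage prioritization), each returning its surviving
records plus the identifiers it removed, so every final candidate is
traceable and every removed item appears in exactly one step's log.
Decisions taken where the design was open:

- The ≥ 30-measurements rule is applied *after* the per-record quality
  predicates (confidence 9, pChEMBL present, human), i.e. it counts
  retained high-quality measurements per target.
- Missing clinical-phase annotation counts as phase 0 (fail-closed: a
  prioritization pipeline prefers false negatives).
- "Antineoplastic" is the ATC prefix L01; the prefix list is configurable
  and a compound with *any* excluded code is dropped, while compounds with
  no ATC annotation are kept (unknown class ≠ antineoplastic).
- Mode-of-action conflicts (agonist/activator on an up-regulated target,
  antagonist/inhibitor on a down-regulated one) *exclude* the pair rather
  than down-weighting it; unknown actions are kept.
- Mouse genes mapping to zero or to multiple human symbols are dropped and
  logged (`unmapped` / `multi-mapped`) rather than expanded, preventing
  double-counted targets.
- Final ranking: stage tier (early < moderate < advanced) — earlier-stage
  targets are upstream of irreversible damage — then best pChEMBL
  descending, then target id.

pChEMBL is −log10 of molar activity: 100 µM ⇔ 4.0, 1 nM ⇔ 9.0.

## Cyst-assay readouts

Per-well cyst area is expressed as a percentage anchored on the plate
controls: forskolin-only swelling wells anchor 100 % and suppressed (or
unstimulated) wells 0 %; which role anchors which end is a configuration
argument since the anchoring convention, not the formula, is
assay-specific. The apoptotic fraction is nuclei-without-actin over total
nuclei. A condition is flagged toxic when nuclei area, nuclei roundness or
apoptotic fraction lies more than z = 3 vehicle standard deviations from
the vehicle mean in the staurosporin-like direction (smaller, less round,
more actin-negative nuclei); metrics with zero vehicle variance are skipped
with a warning. The z = 3 default encodes "clearly outside the vehicle
distribution" for quadruplicate wells; toxicity in such screens is
otherwise judged qualitatively.

## Synthetic-data generator

The generator is first-class code and the pipeline's oracle. It emulates:

- **Counts**: negative-binomial (gamma-Poisson) with gene baselines drawn
  log-normally (log2 mean 9, sd 1.5 → median ≈ 512 counts/gene). With
  2,000 genes this gives ≈ 2M-read libraries, matching the per-gene depth
  of ~30M reads over 20k genes in deep bulk RNA-seq, so the dispersion term
  (default 0.1) rather than shot noise dominates — as in the real assay.
  Per-sample depth varies log-normally (sd 0.15) to exercise CPM/TMM.
- **Archetypes**: 12 planted expression patterns — 5 early, 4 moderate, 3
  advanced, mixing up and down — as per-week weight vectors peaking inside
  their stage window, times the effect size (default log2FC 2 at weight 1),
  25 genes each by default.
- **Aberrant clusters**: 3 planted artifact archetypes of 10 genes. A gene
  whose *only* signal is a single-sample spike can never pass a t-based FDR
  gate (the spike inflates exactly the residual variance its mean shift is
  tested against), so each artifact gene carries a genuine one-group signal
  — which is what makes it differentially expressed — plus a much larger
  spike in one sample of a *different* group that dominates its cluster's
  mean profile and triggers the leave-one-sample-out flag. The spikes are
  deliberately extreme in log space (a single sample must outweigh a group
  log-mean by > 2× the genuine effect); they inflate the spiked sample's
  library, which TMM absorbs — a realistic stress test of normalization.
- **Treatment arms**: treated samples are drawn at the comparator-week
  means with each arm's planted-normalized genes pulled back toward the
  wild-type level by `normalized_fraction` (default 1.0, 4 samples and 40
  genes per arm). Only genes whose archetype weight at the comparator week
  is ≥ 0.5 are eligible for planting: a gene that is flat at the harvest
  week has nothing to normalize there, so planting it would make the ground
  truth unrecoverable by *any* method. Under the default archetypes this
  makes planted normalized genes moderate/advanced-stage.
- **Phenotype**: strictly increasing 2KW/BW means over mutant stages
  (1.5 → 9.0 %, WT 1.2 %), log-normal noise (8 %).
- **Bioactivity database**: every cascade step has items planted to fail
  exactly there (confidence-8 assays, absent pChEMBL, a rat target, an
  under-measured target, non-progression targets, phase-0/1 compounds,
  non-normalized targets, L01 compounds, conflicting modes of action) plus
  six full survivors, each target with 8 compounds × 4 assays. Expected
  survivor sets per step are derived from the construction plan itself,
  never by running the filters, and stored as ground truth. Mouse
  identifiers are Title-case and human symbols upper-case to exercise the
  ortholog-mapping path, including planted unmapped and multi-mapped genes.

**Deterministic regime.** `dispersion = 0` replaces sampling with
`round(mu * 2^jitter)`, where the jitter is a fixed alternating ±0.05-log2
pattern that is zero-mean within every group and gives every gene an
identical within-group variance. Null genes then have exactly zero
log-fold-change (p ≈ 1), planted genes are unambiguous, and the full
pipeline reproduces the planted ground truth *exactly* — the basis of the
end-to-end determinism tests.

**What the generator does not emulate**: gene–gene correlation, GC/length
biases, sample-specific batch effects, sex differences, partial treatment
response heterogeneity, and the long-tailed target/compound distribution of
a real bioactivity database. Passing recovery tests therefore demonstrate
correctness of the statistics and plumbing under the stated noise model,
not performance on real cohorts.

## Problem sizes and defaults

Default runs use 2,000 genes (300 planted + 30 artifact), ~37–49 samples,
and a ~630-record bioactivity table — sizes chosen so a full pipeline run
takes under a second and the 20-seed recovery experiments stay fast while
keeping ≥ 25 genes per cluster and ≥ 30 measurements per surviving target.
The recovery experiments (effect log2FC 2, dispersion 0.1, 4 animals per
group, ~200 planted genes) report mean recall and precision ≥ 0.8 over 20
seeds for both progression and normalized genes.

## Known limitations

- The moderated t is not voom: no precision weights, so low-count genes are
  slightly under-powered relative to the original engine.
- Stage grouping by peak window cannot represent genes dysregulated across
  several stages; they are assigned to their peak stage only.
- The aberrant-cluster rule is a leave-one-sample-out dominance test; other
  plausible operationalizations (robust z on sample contributions) would
  flag slightly different borderline clusters.
- Multi-mapped orthologs are dropped, which under-counts paralog-rich
  families.
- RF significance assumes simple random draws from the background; genes
  are not exchangeable in real data (expression-dependent detectability),
  so the attached hypergeometric p is optimistic there.
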