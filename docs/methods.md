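# Methods

This note documents the statistical models, defaults and design choices
behind `basalshift`, in the order data flow through the pipeline.

## Synthetic study model

All generators are pure functions of a `SimulationConfig` (including its
seed); the same config is byte-reproducible.  Bulk expression is modeled
as Gaussian log2 intensities: per-gene baselines b_g ~ N(8, 1.5²) plus
iid noise N(0, noise_sd²), noise_sd = 1 by default.  A Gaussian model is
appropriate here because every downstream statistic is rank-based
(Mann–Whitney, Spearman, the enrichment walks) or operates on the log
scale; raw negative-binomial counts are generated only for the
single-cell QC fixture.

**Cell-line panel.** 33 luminal and 39 basal lines.  The basal program
(75 genes, led by the six basal cytokeratins KRT5/6A/6B/14/16/17) is
shifted up by `basal_shift_log2` (default 2.0) in basal lines; the
luminal program (68 genes) likewise in luminal lines.

**Paired cohort.** 44 wild-type and 7 *ESR1*-mutant patients by default,
two samples per patient (primary, metastasis) sharing a per-patient,
per-gene random effect N(0, pairing_sd²), pairing_sd = 1.  Mutant
metastases receive the basal shift on the basal program; the immune
program (141 genes, the size of the ESTIMATE immune list) is elevated by
`immune_coupling` × (the sample's realized basal elevation), coupling
0.8 by default.  The planted contrast is therefore visible in the paired
metastasis-minus-primary delta but cancels in cross-sectional averages.

`basal_activity_sd` (default 0) optionally adds a per-sample latent
basal activity.  With the default, the mutant-metastasis shift is the
only basal-program signal — the construction the paired-delta analyses
assume.  Quartile-stratification designs (BCK-high vs BCK-low) need
cross-sample heterogeneity of the basal program to have anything to
stratify, so the workflow layer switches the latent activity on (sd = 1)
for those cohorts; the same latent activity drives the survival
generator's hazard groups.

**Survival.** Event times are exponential with baseline hazard 0.1 per
time unit; the top quartile of latent basal activity (by rank, so the
group is well defined under ties) has its hazard multiplied by
`hazard_ratio_bck_high` (default 2.0).  Censoring is an independent
exponential with rate 0.025, giving roughly 20% censoring — typical of a
mature survival cohort.

**Mutations.** Per sample, truncating and non-truncating counts are
Poisson with means 3 and 4 (so the expected weighted burden is
2·3 + 4 = 10), plus Poisson(1) Silent rows that the burden calculation
must ignore.  Class tokens are drawn uniformly within each class list.

**Chromatin.** Five convergent boundary pairs (left motif "+", right
"−") are planted 200 kb apart, each CTCF footprint co-occupied by all
three cohesin subunits and spanned by a 5-read-pair linkage; three
non-convergent (same-strand) pairs get weak 2-read-pair linkages, and
ten decoy CTCF peaks carry no cohesin.  One TSS is placed inside each
convergent loop and one outside.  The configuration is deliberately
unambiguous: recovery tests expect precision = recall = 1.

## Enrichment statistics

The GSVA-style score uses the Gaussian-kernel ECDF
ẑᵢⱼ = (1/n) Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ) with bandwidth hᵢ = sᵢ/4 (sᵢ the
gene's across-sample SD, ddof = 1).  Zero-variance genes receive
ẑ = 0.5 everywhere rather than being dropped, so the effective gene
universe p is identical for every set.  Per sample, genes are ranked by
ẑ descending with ties broken by gene identifier — this makes scores
invariant to the row order of the matrix and deterministic across
platforms.  Rank weights are |p/2 − r|^τ with τ = 1.  The score is
ES⁺ + ES⁻ ("magnitude_difference", the default of the package the
statistic follows) with the maximum-deviation variant exposed; the two
differ only when the walk has both a positive and a negative excursion.
If every set gene lands exactly at the central rank (weight 0, possible
only for tiny sets at even p), the in-set weights fall back to uniform
for that sample rather than dividing by zero.

The ssGSEA-style score ranks by raw expression, weights set positions by
rank^α with α = 0.25, and sums the running-sum difference over all list
positions without normalization — the convention used for immune
scoring.  Both statistics are verified against literal step-by-step
brute-force evaluations to 1e-12 in the test suite.

Quartile stratification uses linear-interpolation percentiles; samples
at or beyond Q3/Q1 take the extreme label (ties go to the extreme).  A
fully degenerate score vector (Q1 = Q3) labels everything "mid" with a
warning instead of labeling every sample high and low simultaneously.

## Differential expression and signatures

The per-gene test is the two-sided Mann–Whitney U: exact null
distribution when the combined group size is ≤ 20 and the gene is
tie-free, otherwise the normal approximation with tie correction.  The
consumer of this module is a gene list, not an effect estimate, so a
distribution-free rank test is preferred over moderated-variance models.
Fold changes are mean differences on the log2 scale.  Genes with zero
variance across both groups get p = 1, fold change 0, and a flag.
Multiplicity is controlled by an in-package Benjamini–Hochberg step-up
(verified against both a brute-force evaluation of the step-up formula
and statsmodels).

"Top-N increased" lists are ranked by fold change among genes
significant at q < 0.05 (the gate is configurable, including off), with
ties broken by smaller p then lexicographic gene id.  The ranking key
for such lists is genuinely underdetermined in the field; fold change
was chosen because the lists feed set-intersection steps where effect
direction, not significance ordering, is what matters.

## Subtype calling and concordance

Centroids are per-gene medians (robust to outlier reference samples;
means available).  Calls use Spearman correlation over the model gene
list, which makes them invariant to any strictly monotone transform of
the profile — log/linear mismatches cannot flip a call.  The confidence
readout is max(ρ, 0) normalized over subtypes; it is a monotone summary
of relative correlation, not a calibrated posterior, and is flagged
undefined when no centroid correlates positively.  Concordance across
comparisons is strict sign agreement (log2FC > 0 in every comparison, or
< 0 in every comparison) with an optional magnitude threshold; the
boundary is strict, so a zero fold change is always "inconsistent".

## Pathway comparisons and immune scores

Per-set comparisons are Mann–Whitney on per-sample enrichment scores
(or per-patient delta scores when a pairing exists), BH-corrected across
the set collection, with "enriched" meaning q < 0.05 *and* a higher
median in the group of interest (direction-aware).  The intersection
step requires enrichment in every comparison; Venn region counts are
reported for bookkeeping.  Immune-cell-type scores are the mean across
signature genes of per-gene z-scores (zero-variance genes skipped with a
warning) — the simplest transform consistent with published
cell-type-signature scoring.  TMB is 2·truncating + non-truncating with
the truncating class {Nonsense_Mutation, Frame_Shift_Del,
Frame_Shift_Ins, Splice_Site} and non-truncating {Missense_Mutation,
In_Frame_Del, In_Frame_Ins, Nonstop_Mutation}; every other token
(Silent, UTRs, …) is excluded.

## Survival analysis

Kaplan–Meier uses the product-limit estimator with subjects censored at
an event time counted in that time's risk set.  The log-rank test is the
standard O−E statistic with hypergeometric variance, df = 1.  Cox
regression maximizes the partial likelihood by Newton–Raphson with
Efron's tie correction (Breslow by flag), converging when
max |Δβ| < 1e-8 within 50 iterations; Wald 95% CIs are exp(β ± 1.96·SE).
Monotone likelihoods (complete separation) surface as a non-convergence
flag carrying the last iterate rather than an exception.  The score test
at β = 0 is exposed separately; on tie-free two-group data it reproduces
the log-rank chi-square exactly, which the tests assert to 1e-8.  All
three estimators are cross-checked against lifelines.

## Chromatin logic

A CTCF peak becomes a boundary when ≥ 2 of the three cohesin subunit
tracks overlap it (the count is configurable; "co-occupied by subunits"
does not pin down a number, and 2-of-3 tolerates one failed track).
Overlap is literal (window 0) by default; a slack window is exposed
because real peak calls need it.  Motif strand comes from the unique
overlapping motif, else "unknown".  Linkages whose anchors hit two
distinct boundaries become loops with counts summed per boundary pair;
strong means strictly more than 3 read pairs, convergent means left "+"
/ right "−".  Peak-to-gene distances are signed from the peak midpoint
(a summit column, when present, should be converted to a 1 bp interval
upstream of this module), strand-aware so positive means downstream of
transcription; promoter is |d| ≤ 3000 bp, flank 3000 < |d| ≤ 50000 bp,
nearest TSS wins with lexicographic tie-break.

## Single-cell QC

One fixed pass: genes detected (count > 0) in fewer than 20 cells are
removed first; then, on the gene-filtered matrix, cells detecting fewer
than 300 or more than 8000 genes, or with a mitochondrial count fraction
above 0.45, are removed.  "Detected" is count > 0; mitochondrial genes
are identified by the configurable symbol prefix "MT-".  The filters are
not iterated — a cell removal never re-triggers the gene filter.

## Problem sizes and calibration checks

The shipped default seed is 20220419.  The calibration suite runs at
sizes chosen to make Monte-Carlo error small relative to the bands being
checked while staying desk-scale: 100 random toy matrices (≤ 30 genes ×
≤ 8 samples) for oracle equivalence of the enrichment statistics;
20 + 20 patient pairs for the planted-delta genotype contrast, with 200
null replicates (reduced 300-gene universe) for the uniformity check of
its p-values; 2000 replicates at n = 200 for log-rank type-I error;
n = 500 for Cox hazard-ratio recovery; 500 null replicates for the
specificity of the three-way pathway intersection.  The null
intersection rate is expected near (α/2)³ — three independent one-sided
q < 0.05 events — so observing zero hits in 500 replicates is the norm.

## What passing tests do and do not show

The generators produce Gaussian, independent-gene expression with exactly
planted, homogeneous effects; real tumor data have correlated gene
modules, batch structure, varying purity, and signatures whose member
genes respond heterogeneously.  Recovery at the planted effect size
therefore demonstrates that the statistics and their wiring are correct,
not that the pipeline has a particular power on real cohorts.  Likewise
the chromatin generator plants unambiguous boundary configurations;
precision/recall of 1.0 validates the calling logic, not performance on
noisy peak calls.  The subtype caller's confidence is a normalized
correlation, not the posterior probability of the published caller it
stands in for.  Cross-study batch correction, peak calling from reads,
ChIA-PET read-pair processing and deconvolution-style immune estimation
are all out of scope.
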