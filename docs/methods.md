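# Methods

This note documents the models, numerical choices and limitations behind
`mirnorm`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Working scale and model assumptions

All stability computations operate directly on Ct. Under the usual qPCR
assumption of amplification efficiency 2, Ct is −log2 of template
abundance up to an assay constant, so differences of Ct are log2 expression
ratios and the SD of a log-ratio equals the SD of the corresponding Ct
difference. No efficiency correction is applied; if per-assay efficiencies
were available, Ct values should be rescaled before entry.

The data model is a wide matrix of one Ct per assay per sample (technical
replicates are assumed already collapsed upstream), with an explicit
detected/undetected mask. Undetected wells are *never* imputed:

- the candidate filter averages detected values only (imputing the cycle
  ceiling would make the "mean Ct" threshold depend on an arbitrary
  constant);
- stability algorithms require complete cases — a candidate with any
  undetected well after filtering is dropped with a logged warning. The
  Ct < 35 filter makes such drops rare by construction, and silent
  imputation would bias every pairwise SD downward.

## Quality control

**Inter-plate calibration.** The instrument does not document a
calibration formula, so the standard mean-centering is used: the offset of
plate *p* is the difference between its inter-plate-calibrator (IPC) mean
and the pooled IPC mean over all wells, and all Ct on the plate are reduced
by it. Properties: IPC plate means are exactly equalized, within-plate
differences are preserved exactly, offsets weighted by well count sum to
zero, and the transform is invertible. A single plate is the identity.

**Spike-in group checks.** Each isolation/RT spike-in is tested by one-way
ANOVA across clinical groups; failure at α (default 0.05) flags
group-correlated technical variation. A degenerate input with zero total
variance is reported as pass with p = 1 (flat data carries no evidence of
a group effect, and NaN would poison downstream report logic).

**Detection filter.** An assay is a candidate iff its mean detected Ct is
strictly below the threshold (default 35 cycles) in the pooled tumor
partition *and* in controls. Spike-ins and negative controls never
qualify. The strict inequality makes the boundary testable (34.9 in, 35.0
out).

## Stability algorithms

All four are implemented here (none wraps an external stability tool), and
each is verified against an independent loop-based oracle to 1e-12.

**Pairwise-SD statistic.** Entry (j,k) is the sample SD (n−1 denominator)
of per-sample differences Ct_j − Ct_k. Per-sample additive offsets cancel
in the differences, which is the formal sense in which these methods
"don't need a normalizer to find a normalizer".

**Comparative ΔCt** is the row mean of that matrix. By construction it
equals geNorm's *M* value before any elimination — the identity is
asserted in the tests at 1e-12 and explains why the two methods' rankings
often agree.

**geNorm** recomputes *M* on the shrinking candidate set, eliminating the
largest-*M* gene each round (ties eliminate the lexicographically larger
id). A gene's reported value is its *M* at elimination; the surviving pair
shares the final pairwise SD and tied rank 1.5 — the midpoint of ranks 1
and 2, preserving the rank sum, since downstream aggregation needs a
numeric rank for each gene. The pairwise-variation criterion for choosing
*how many* reference genes is out of scope: the workflow selects a single
normalizer.

**BestKeeper** reports the arithmetic mean Ct, the mean absolute deviation
(MAD) around it — BestKeeper's "SD [±Ct]" — and CV% = MAD/mean·100, ranking
by MAD; the ordinary sample SD is carried as an extra column. MAD was
chosen as the ranking statistic because it is the original BestKeeper
definition; which variant a given aggregator web tool uses is not
documented anywhere authoritative. BestKeeper is deliberately *not*
shift-invariant: it measures total dispersion including shared per-sample
variation. The synthetic-data tests assert the direction of that effect
rather than "fixing" it.

**NormFinder.** The grouped variance-decomposition model, in five steps:
(1) center each sample by its mean across candidate genes (this removes
per-sample offsets exactly); (2) per gene i and group g, take the group
mean d_ig and within-group sample variance s²_ig of the centered values;
(3) center d_ig per gene across groups; (4) shrink toward zero,
d*_ig = d_ig·γ/(γ + s²_ig/n_g), where γ ≥ 0 is a method-of-moments
estimate of the between-group variance of the biases across genes — after
centering over G groups, E[d_ig²] ≈ γ(G−1)/G + (1−1/G)s²_ig/n_g, which is
solved for γ and truncated at zero; (5) stability is the mean over groups
of |d*_ig| + SE(d*_ig), with SE² = γ(s²_ig/n_g)/(γ + s²_ig/n_g), the
posterior variance of the shrunken bias.

Numerical choices worth stating: s²_ig is the plain within-group sample
variance of the centered values — the small-sample covariance correction
induced by step (1) (centered residuals are weakly negatively correlated
across genes) is not applied, a simplification validated by the
parameter-recovery test (the zero-bias low-noise gene wins ≥95% of 200
replicates at 6 genes × 40 samples; genes with a planted 1-Ct bias never
win). When γ̂ = 0 the shrinkage maps every bias and its SE to zero, which
cannot rank genes, so the estimator falls back to the ungrouped variant —
the intra-gene SD of sample-centered values — and logs it. The default
grouping is cases-pooled-vs-controls, matching the question "stable over
the entire sample range"; per-subgroup grouping is available.

**Aggregation.** The comprehensive rank is the geometric mean of the four
per-algorithm (midpoint-tied) ranks; the final ordering breaks geometric-
mean ties lexicographically by assay id so every output is a strict 1..n
permutation and byte-reproducible. The top-k overlap partitions the union
of per-algorithm top-k lists into Venn regions, with boundary ties inside
an algorithm's list resolved by the same (rank, assay id) order.

## Expression statistics

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the arithmetic
mean ΔCt of the baseline group (default control), hence the baseline
group's geometric-mean RQ is exactly 1; RQ = 2^−ΔΔCt. Changing the
baseline rescales all RQ by one positive factor and cannot change test
decisions made on log RQ.

Group tests are the classic unadjusted forms: equal-variance Student
t-test for the reference's BC-vs-control check (no Welch correction, no
multiplicity adjustment across the candidates — each candidate is reported
with its raw p), and one-way ANOVA with Tukey HSD on log2 RQ = −ΔΔCt.
Testing on the log scale is the variance-stabilizing choice for
fold-changes; summaries are reported as mean RQ ± SEM on the linear scale
because that is how such results are conventionally plotted. Whether
linear-scale or back-transformed error bars are "right" is genuinely
underdetermined; the per-sample table carries ΔΔCt so either can be
recomputed. Grouping schemes: `full` (every subgroup + control),
`Ta-pooled` (TaG1/TaG2/TaG3 merged), `NMIBC-vs-MIBC` (Ta/T1 vs T2+/T3+,
control separate). A scheme yielding any group below two samples raises an
error naming the group; the validation workflow catches this per scheme
and reports "not estimable" instead of aborting, because the default
validation cohort legitimately contains a single T3G3 patient.

## Synthetic cohorts

The generator draws Ct_ij = μ_i + group_offset_i(g(j)) + s_j + ε_ij with
s_j ~ N(0, sample_effect_sd²) shared across the panel and
ε_ij ~ N(0, σ_i²); wells above the censoring threshold (default 40 cycles,
the conventional late-Ct cutoff) are emitted as undetected. Normal noise
on the Ct scale (log-normal expression) is the standard qPCR error model.

The default screening cohort mirrors a realistic study: 15 controls plus
35 tumor samples (10 TaG1, 8 TaG3, 5 T1G3, 12 T2G3) on a 40-assay panel —
one designated stable normalizer (σ = 0.1 Ct, no group effect), a target
with a severity-monotone expression increase (Ct shifts 0 / −0.5 / −1.0 /
−1.5 / −1.0 for control / TaG1 / TaG3 / T1G3 / T2G3, strongest in T1G3),
33 unstable competitors (alternating noise-driven, σ 0.8–1.3, and
bias-driven, 0.5–2.0-Ct group effects with alternating direction of
dysregulation so dysregulated genes do not share one pattern and mutually
cancel in pairwise differences; three are expressed too late to pass the
Ct filter), four spike-ins and a negative control. Per-sample technical SD
defaults to 1.0 Ct — large, as expected for urine input normalized by
volume rather than RNA mass. The validation cohort uses the same panel
with 57 controls and 153 tumor samples across the full stage/grade
spectrum. These effect sizes are scenario parameters recorded in the
emitted `GroundTruth`, not estimates of any real dataset.

What passing tests on these cohorts shows: the pipeline recovers a
genuinely stable assay among realistically unstable competitors, at
realistic sample sizes, with calibrated error rates. What it does not
show: robustness to features the generator omits — hemolysis-like
correlated contamination, amplification-efficiency differences between
assays, plate-position effects, non-normal heavy-tailed noise, or
co-regulated miRNA families sharing one biological program.

## Determinism

Every source of randomness flows through an explicit integer seed
(`numpy.random.default_rng`); ranking ties everywhere break
lexicographically by assay id; result tables carry a provenance header
(package version, seed, config hash — no timestamps) and fixed 6-
significant-digit serialization, so a workflow rerun with the same config
and seed reproduces the output bundle byte for byte.

## Problem sizes

The acceptance script uses 100 screening cohorts (50 samples × 40 assays)
for recovery, 50 validation cohorts (210 samples) for the stability-check
pass rate, and 1000 null replicates each for t-test and ANOVA calibration —
sizes at which the binomial noise on every reported rate is ≤ ~2 percentage
points while the whole script runs in a few minutes on one core.
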