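# Methods

## Scales and standardization

All expression computations operate on log2(TPM+1) values. Gene-wise
z-scoring uses the sample standard deviation (n−1 denominator), the
convention of most expression toolkits. Fitting and applying the scaling
are separate operations: cohort-wide labeling scales over the cohort being
labeled, while the classifier freezes scaling parameters estimated on its
training samples only and applies them unchanged to new data — the two
uses are deliberately distinct so no test-set statistics leak into model
building. Zero-variance genes map to z = 0 rather than being dropped,
keeping matrix shapes stable; they are excluded from program candidacy
automatically because their correlation with every TF is defined as 0.
Missing expression values are an error, not an imputation target: the
pipeline assumes complete quantification upstream.

## TF labeling rules

The strict rule assigns the subtype of the top TF iff the top z-score
exceeds the runner-up by at least the margin δ (default 0.3 z-units,
*inclusive*, since the requirement is "at least" a margin) and the top
z-score is non-negative (inclusive: a maximum of exactly 0 counts as "not
all-negative"; the boundary convention is ours and is documented rather
than claimed). The relaxed rule is a bare argmax; ties break
deterministically by the configured TF order (NEUROD1, ASCL1, POU2F3,
YAP1) and are flagged in the output for audit. Strict is a refinement of
relaxed: whenever strict assigns, relaxed agrees.

## Program derivation

"Exclusive association" is operationalized as argmax candidacy: each gene
may enter only the program of the TF it correlates with most strongly over
the training samples. Genes whose best correlation is non-positive are
dropped by default (programs model *activated* downstream targets;
configurable off). Within a TF, genes rank by descending correlation with
lexicographic gene-ID tie-break, making derivation deterministic across
platforms. The four TF genes themselves are always excluded. Whether a
minimum correlation *gap* between best and second-best TF should also be
required is genuinely open; the argmax rule is this implementation's
definition and increasing k provably extends programs as prefixes.

## Classifier

One-vs-rest linear soft-margin SVMs (squared hinge, primal solver, hence
deterministic) over the 4×k program genes; prediction is the argmax of the
four decision values with ties broken by class order. The nested CV uses
outer 4-fold CV on 5 random stratified splits (20 runs) with inner 3-fold
CV selecting the cost from a log2 grid 2⁻¹⁰…2⁵ (which contains
2⁻⁵ = 0.03125, matching the published final cost of 0.031 to its printed
precision). The inner selection criterion is mean macro balanced accuracy,
chosen because the subtype distribution is imbalanced (SCLC-P is roughly a
quarter the size of SCLC-A). Programs and feature scaling are re-derived
on each outer-training part only; corrupting outer-test samples provably
changes neither the selected features nor the cost (tested). The final
model refits on the full training set with the feature group of the run
whose outer balanced accuracy is maximal (ties → lowest run index). Models
serialize to a self-contained JSON document (features, scaling, weights,
cost, class order).

Per-class metrics are one-vs-rest (sensitivity, specificity, PPV, NPV, F,
balanced accuracy); macro values are unweighted class means; undefined 0/0
ratios are reported as NaN and excluded from macros with a warning.

## Consensus

For strictly labeled samples, consensus requires strict = ML; for
borderline samples, relaxed = ML. The agreement table is tested with a
Pearson χ² test of independence without continuity correction (the 4×4
table has df = 9).

## Signature analysis

The coherence score is defined here as the mean off-diagonal pairwise
Pearson correlation among a signature's genes present in the matrix; the
filter threshold (default 0.2, exclusive) and the ≥ 50% gene-coverage
requirement are configurable. Differential testing uses two-sided Wilcoxon
rank-sum tests (normal approximation with tie and continuity correction)
for the six subtype pairs, Bonferroni-corrected *within* the signature
(×6, capped at 1) — the retention rule (≥ 3 of 6 adjusted p < 0.05) is
applied per signature, so no cross-signature correction is layered on top.
Representative selection among signatures describing one process uses the
one-way ANOVA F across subtypes (ties → lexicographic name). Top-scorer
composition takes the ⌈fraction·n⌉ highest scores with ties at the cutoff
broken by sample ID.

## Genomic association

Alteration frequency counts a sample once per gene regardless of how many
alteration classes hit it; the oncoprint filter keeps genes with overall
frequency strictly greater than 5%. The Fisher exact r×c test defines the
two-sided p by the probability-mass criterion — the total null probability
(fixed margins, multivariate hypergeometric) of tables no more probable
than the observed one — computed by depth-first enumeration of all tables
with the observed margins (log-sum-exp accumulation; ties in probability
detected with a relative tolerance of 1e−10). Above a configurable
enumeration bound (default 10⁷ tables) the test switches to Monte Carlo
sampling of fixed-margin tables with a logged seed and replicate count,
using the (hits+1)/(reps+1) estimator. For 2×2 inputs the result equals
the classical two-sided Fisher test to ~1e−14 (tested against an
independent implementation).

## Survival

Kaplan–Meier medians are the smallest time with S(t) ≤ 0.5 (not-reached
reported as such, never an error) with log-log confidence intervals — a
common default; the method behind published median CIs is typically
unstated. Cox models use Efron tie handling and Wald p values; categorical
covariates are dummy-expanded against an explicit reference level, with
subtype contrasts conventionally reported against SCLC-P. Both a 4-level
subtype factor and a P-vs-rest binary encoding are supported, since
published multivariate models have used either. OS time construction
(diagnosis-vs-biopsy origin) is a data-preparation concern upstream of
this package; records arrive with precomputed positive times.

## Synthetic cohort generator

The generator plants exactly the structure the pipeline assumes, under
these default study conditions: n = 400 samples; subtype proportions
A/N/P/Y = 0.33/0.32/0.13/0.22 (mirroring reported strictly-labeled SCLC
cohorts); 20 program genes per TF at a target correlation of 0.7 to their
TF; 400 independent background genes; 28% borderline samples (mirroring
the reported fraction of strict-rule-unassigned cases); subtype-enriched
alterations (near-universal TP53/RB1, MYCL amplification enriched in
SCLC-A at 11.5% vs 1.3–5.1% elsewhere, RET enriched in SCLC-Y); and
exponential OS with per-subtype median months A 13.8 / N 10.1 / P 7.3 /
Y 9.9, a male-sex log-HR of +0.35 and a T-effector-score log-HR of −0.30
per z-unit, censored by an exponential (mean 40 months) with
administrative cutoff at 60 months.

Expression is Gaussian on the log scale (a Student-t(5) option exists to
stress-test rank-based stages): each TF gene is its subtype indicator ×
`tf_shift` (default 2.0) plus `tf_noise_sd` × noise, offset to a
non-negative log2(TPM+1)-like baseline. `tf_noise_sd` = 0.4 was sized
analytically so that the strict rule's 0.3-z margin separates
non-borderline samples reliably at the default shift: after cohort
z-scaling (whose variance includes both the between-subtype shift and the
co-elevations of borderline samples), the per-competitor margin-failure
probability Φ((δ − Δz)/(√2·σz)) stays below ~1% for every subtype pair.
Program genes are generated as ρ·(standardized TF) + √(1−ρ²)·noise, which
makes their population correlation to the TF exactly ρ. Borderline samples
get a second TF co-elevated to within 0.2 *cohort z-units* of their own
TF — below the strict margin, so the strict rule rejects them while the
relaxed argmax still recovers the planted label; this mirrors the
"twilight zone" tumors that motivate the consensus step. All randomness
flows from one seed through per-component sub-streams (expression /
alterations / survival), so adding genes does not perturb survival draws.

What the generator does *not* emulate: FFPE artifacts, sequencing-depth
noise, tumor purity, correlated background genes, batch effects, or
heavy-tailed outliers (unless the t-noise flag is set). Passing recovery
tests therefore demonstrates that the pipeline's logic is correct under
its own statistical assumptions — not that real cohorts are this easy.

The tiny worked example (12 samples × 25 genes, three per subtype plus one
planted borderline case) is fully deterministic and hand-checkable; its
strict/relaxed calls, k = 2 programs and Y-signature scores are frozen as
golden files in the test suite.

## Problem sizes in tests and the acceptance script

Module-level tests use a compact cohort (160 samples, 120 background
genes); end-to-end recovery checks use five default cohorts (n = 400) with
the full 20-run nested CV; null calibration uses 1,000 ten-gene signatures
on a 4×30-sample null matrix; the no-signal collapse check runs one 4-fold
CV repeat at n = 400 with `tf_shift` = 0. These sizes keep the complete
run in the minutes range on a single CPU while leaving every statistical
conclusion comfortably away from its threshold.

## Known limitations

- The coherence score reproduces the *idea* of the published
  coherence-filtered compendium scoring; the original score's exact
  formula is not public, so the definition here (mean pairwise Pearson) is
  explicit and the threshold configurable.
- The Fisher r×c enumeration is exponential in table size; large tables
  fall back to Monte Carlo (seeded, with replicate count reported).
- Wilcoxon tests use the normal approximation; for very small groups an
  exact test could differ near the significance boundary.
- No kernel SVMs, probability calibration, batch correction, or
  proportional-hazards diagnostics — deliberately out of scope.
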