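# Methods

This note documents the statistical model behind each pipeline stage,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design
choices that were genuinely open.

## Differential expression

The count test models per-sample counts of a feature as negative
binomial with a common dispersion φ shared across features.  Library
sizes are normalized by median-of-ratios factors (each sample's median
ratio to the per-feature geometric-mean reference, computed over
features expressed in every sample; total-count factors are the
fallback when fewer than five such features exist).  φ is estimated by
the method of moments — the 10%-trimmed mean over features and
conditions of (s² − m̄)/m̄², floored at zero — which is accurate when
several hundred features are available and degrades gracefully to a
Poisson model on equidispersed data.  The test itself conditions the
disease-group sum on the two-group total: group sums are NB with size
n<sub>i</sub>/φ and mean n<sub>i</sub>μ̂ (binomial conditional in the
Poisson limit), and the two-sided p-value sums the conditional
probabilities of all splits no more probable than the observed one.
Totals above 2 × 10⁶ switch to a normal approximation.  Fold changes
are log2 of the group means of normalized counts with a prior count of
0.5.  P-values are deliberately unadjusted — this stage is a screen at
raw p < 0.05, and multiple-testing control enters downstream.  A Welch
t-test on log2(FPKM + 1) is available for datasets without counts; it
is a config switch, not a silent fallback.

Calibration of the exact test was checked by simulation: on 2,000 null
NB features (8 vs 8) the flagged fraction at p < 0.05 lands within
0.05 ± 0.02, and a planted four-fold change is detected in ≥ 95% of
features at moderate dispersion (φ = 0.1).

## Correlation screen

Pearson correlations are computed per condition on log2(FPKM + 1), not
on raw FPKM.  This was the one place the implementation deliberately
departs from the naive reading of "correlate the normalized values":
FPKM values are heavily right-skewed, and at n = 8 per group a single
high-expression sample dominates the raw-scale sample correlation —
empirically the permutation null (below) becomes so heavy-tailed that
genuinely rewired pairs are undetectable.  The log transform is the
standard variance-stabilizing choice and preserves the sign structure
the screen tests for.  The raw scale remains available as
`corr_scale: linear`.

Significance uses the exact t-transform null, t = r·√((n−2)/(1−r²))
with n − 2 degrees of freedom, two-sided; the required sign (negative
for miRNA-involved pairs, positive for mRNA–lncRNA) is enforced as a
separate filter rather than folded into a one-sided test, because the
screen's contract is "significantly correlated AND correctly signed".
Features constant within either condition are excluded from pairing
(Pearson is undefined there) with a logged count.

## Permutation differential-correlation test

The null scheme permutes condition labels across all samples,
preserving group sizes, and recomputes both correlations; the p-value
is the literal exceedance frequency — zero is a possible value, and no
pseudocount is added by default (a `(count+1)/(N+1)` mode exists for
FDR stability on request).  The comparison is two-sided on |Δ| by
default: a gain and a loss of correlation are both biologically
meaningful; the printed one-sided form is a config switch.  With 8 + 8
samples only C(16, 8) = 12,870 distinct label splits exist, so the
implementation enumerates all of them whenever that count does not
exceed the requested permutation number (`permutation_mode: auto`), and
otherwise samples splits uniformly with replacement from a per-pair
stream seeded by the global seed and a hash of the pair ids (so results
do not depend on the order pairs are processed).  Sampled splits that
produce a constant sub-vector are redrawn, with a bounded number of
rounds.  An alternative pooled null — deltas of randomly drawn
same-type feature pairs — is available via `permutation_scheme:
pooled`; label permutation is the default because it conditions on the
pair's own data.  FDR is Benjamini–Hochberg within each pair-type
stratum (the three pair classes have very different counts and effect
distributions); pooled adjustment is a config switch.

Two properties of this test at small n are worth knowing.  First, for
a pair that is genuinely coupled in one condition, the label-permuted
null is intrinsically wide (mixed groups inherit partial coupling), so
power at 8 + 8 is modest unless the pair also differs in mean — pairs
whose two members both carry a between-condition shift have tight
nulls and near-zero p-values.  The screening strategy is therefore at
its strongest exactly where it is pointed: at differentially expressed
ceRNA triplets.  Second, pairs enter the permutation stage only after
passing the per-condition screen, so null p-values at this stage are
not uniform (they are selected for large single-condition |r|); the
FDR gate is applied to this selected population, as the screening
design dictates, and the end-to-end false-positive rate is what the
negative-control tests measure.

## Triplet assembly and categories

A triplet qualifies in a condition when its three pairs are all
FDR-significant differential pairs and all passed that condition's
sign/significance screen.  The assignment of a triplet to "disease" or
"normal" is not uniquely dictated by the screening design; requiring
all three pairs to pass in the same condition is this package's rule,
chosen because it makes the emitted triplet a complete, internally
consistent ceRNA signature for that condition.  A triplet may qualify
in both conditions and is then reported once per condition.  Category
labels count DE members (T*/NT* with index 1–3); the summary table's
Total row counts distinct DE elements across categories, not column
sums, since one gene can sit in many triplets.

## Enrichment

Upper-tail hypergeometric p-values are computed in log space via the
survival function; agreement with brute-force enumeration is exact to
1e−12 over every consistent configuration with N ≤ 12.  The background
defaults to the annotation universe (genes annotated to at least one
term), with an option for all measured mRNAs.  The query is the DE
mRNAs of triplets that contain at least one DE miRNA or lncRNA.  The
engine is class-agnostic: functional classes are an input mapping
(class → term ids), and candidates are query genes of enriched,
class-mapped terms.  No ontology-graph propagation is applied — the
annotation is taken as given.

## Classification

SVMs use conventional fixed hyperparameters — cost 1, polynomial
degree 3, kernel scale 1/n_features on standardized input, coef0 = 0 —
exposed in the config but not tuned; there is no hyperparameter search
by design.  Leave-one-out evaluation standardizes each training fold
with its own statistics only (no leakage), guards zero-variance
features with unit scale, and records the held-out decision value.
Class weights are balanced: leaving one sample out makes its class a
minority in every training fold, which would otherwise bias the
decision values systematically against the held-out class and drag the
null AUC below 0.5; with balancing, the permuted-label LOO AUC averages
0.50 within ±0.03 at n = 16.  AUC is the Mann–Whitney statistic with
ties counted 1/2, computed from the continuous decision values.  All
selection gates are strict (> 0.75): a class of candidates must pass
jointly before members are scored individually (the per-class reading;
an all-candidates joint gate is a config switch), and the lncRNA/miRNA
lists draw only from triplets containing a selected gene.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
log2-scale feature baselines μ ~ N(3.5, 1.5²), per-sample biological
noise with σ = `noise_sd` (default 0.3 log2 units — the scale of
replicate variation in homogeneous bulk tissue, and small enough that
the planted couplings survive the exponentiation to the FPKM-like
scale, where negative correlations attenuate more than positive ones),
FPKM-like values 2^log2, and Poisson counts at mean
FPKM × depth × per-sample library factor (depth 20, library-size CV
0.15).

Each planted triplet is miRNA-coupled in exactly one condition
(alternating disease/normal): a latent N(0, 1) profile u drives the
miRNA, the two targets receive −c·u plus residual noise scaled by
√(1 − c²) with c = `coupling_strength` (default 0.9), and the two
target residuals share a common component (`target_residual_corr`,
default 0.5) reflecting co-regulation of ceRNA partners beyond the
shared miRNA — giving log-scale correlations of −c for the miRNA pairs
and c² + (1 − c²)·ρ ≈ 0.9 for the target pair, all three of similar
strength.  In the inactive condition the three profiles are
independent.  All three members of each planted triplet receive the
between-condition mean shift `de_log2fc` (default 2, random sign):
planted triplets emulate fully differentially expressed ceRNA
triplets, which is also the regime where the permutation test has its
power (see above).  Additional features are shifted at random up to
`fraction_de` (default 0.1).  The interaction catalog contains the
planted miRNA-target pairs plus 150 random decoys; the annotation
contains one term over-representing the planted mRNAs (mapped to a
"disease_related" class) plus 30 random background terms.

What the generator does *not* emulate: read-level sequencing and
alignment artifacts, transcript-length effects in FPKM, heteroskedastic
mean-variance trends, correlated background co-expression modules, or
batch structure.  Passing tests therefore demonstrate that the
pipeline recovers the planted signature under its own model assumptions
at realistic sample sizes and controls its false-positive rate on
matched nulls — not that it is robust to every failure mode of real
sequencing data.

## Problem sizes and defaults

Default study conditions: 200 mRNA / 20 miRNA / 50 lncRNA features,
8 vs 8 samples, 5 planted triplets.  The demo and test configurations
use 10,000 permutations per pair (1,000 for the null-calibration
replicates); `PipelineConfig.n_permutations` defaults to 10⁶ for
production runs where per-pair p-values below 1e−5 matter.  At the
default sizes a full pipeline run takes ~15 s on one CPU.

## Known limitations

* Power of the label-permutation test at 8 + 8 samples is modest for
  pairs without mean shifts; larger designs or the Fisher-z style
  analytic comparison (not implemented as a primary path) would be
  needed for purely correlational rewiring.
* The common-dispersion DE test has no per-feature dispersion
  shrinkage, no covariates and no paired designs; it is a screen, not a
  general DE framework.
* Pearson correlation captures only monotone-linear coupling; no
  partial-correlation or conditional-independence refinement is
  attempted, so triplets are correlational signatures, not causal
  claims.
* With p-values returned as literal zero frequencies, BH q-values of
  zero arise; ranking within the significant set then relies on the
  observed |Δ|.
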