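# Methods

## The comparison and its model

Every analysis in `aneumir` is a paired comparison of one aneuploid cell
line against its isogenic parental diploid, starting from integer
feature-by-sample count matrices (one per assay: miRNA and mRNA). Counts
for feature *i* in sample *j* are modelled as negative binomial,

    K_ij ~ NB(mean = s_j · q_i,   variance = mean + phi_i · mean^2)

with per-sample size factors *s_j* (median-of-ratios), a per-feature mean
*q_i*, and a per-feature dispersion *phi_i*. The condition effect is
estimated with a per-feature GLM with log link,

    log E[K_ij] = log s_j + x_j' * beta

where *x_j* holds an intercept, the condition indicator
(aneuploid vs parental) and, in the paired design, replicate/batch
indicator columns. The reported log2 fold change is the condition
coefficient divided by ln 2 — an unshrunk maximum-likelihood estimate. Its
Wald statistic (coefficient over the square root of the inverse Fisher
information) is referred to the normal distribution, two-sided. Features
are called deregulated when |log2FC| >= 0.6 (inclusive) at BH-adjusted
p < 0.05 (strict).

Conventions worth stating because reasonable alternatives exist:

* The mean-count filter keeps features whose **mean raw count over all
  samples of the comparison** is >= 10, inclusive; it runs after size
  factors are estimated on the full matrix (factors are more stable with
  all features) and before testing and BH adjustment.
* No fold-change shrinkage: the +/-0.6 call threshold applies to the plain
  MLE coefficient.
* Independent filtering and outlier replacement (Cook's-distance style)
  found in reference DE packages are deliberately not implemented.
* Non-converged IRLS fits (tolerance 1e-8 on the coefficient change,
  maximum 100 iterations; linear predictor clipped at +/-50) are flagged,
  get p = NA and are excluded from the BH denominator.
* BH adjustment excludes NAs from the number of tests; p-values outside
  [0, 1] are rejected.

## Dispersion estimation

With three replicates per condition, per-feature dispersion estimates are
the weak point of any NB analysis, and the design here was genuinely open.
The estimator proceeds in three steps:

1. **Method of moments.** On normalized counts, the variance is pooled
   within condition (so real condition effects do not inflate it) and
   phi_raw = max(phi_min, (var - mu) / mu^2), phi_min = 1e-8.
2. **Trend.** A log-linear trend in the reciprocal mean,
   phi_trend(mu) = exp(a + b/mu), is fit across features by a Gamma GLM
   with log link, with one refit after discarding features whose ratio to
   the first trend falls outside [1e-4, 15]. The 1/mu term captures the
   extra-Poisson scaling at low counts.
3. **Empirical-Bayes shrinkage with an adaptive weight.** The spread of
   log phi_raw around the trend is decomposed into per-feature sampling
   noise — by the delta method, sd(log phi_raw) ~ sqrt(2/d) * (1 + 1/(phi
   mu)) for d residual degrees of freedom, evaluated at the trend — and a
   feature-to-feature prior variance, estimated robustly (MAD) and floored
   at 0.25^2. Each feature's estimate is pulled toward the trend in
   proportion to its noise share; raw values are clamped to within a
   factor e^3 of the trend first so floored or wild estimates cannot
   dominate.

A fixed shrinkage weight was tried first and rejected: with 4 residual
degrees of freedom the retained half of the estimation noise propagates
into the Wald denominator and visibly distorts the null distribution of
p-values (KS distance ~0.08 at 5,000 features), while the adaptive weight
leaves the null calibrated (KS uniformity holds in ~97% of simulated null
datasets; with the dispersion fixed at its true value the Wald p-values
are uniform, so the residual deviation is attributable to estimation).
When features genuinely share a dispersion, the adaptive weight
automatically approaches trend-only behaviour; when they do not, the floor
keeps a per-feature component.

## Dosage analysis

Features are grouped by chromosome using the annotation, and each gained
(non-disomic) chromosome's log2FC distribution is compared against all
features on disomic chromosomes of the same assay and cell line with a
two-sided Mann–Whitney–Wilcoxon test — exact null distribution when
n + m <= 20 without ties, normal approximation with tie and continuity
correction otherwise. Sidedness is not obvious a priori; two-sided is the
conservative choice. Features on any non-disomic chromosome are excluded
from the background to avoid contaminating it. Three modes exist: per
gained chromosome (default), pooled (all gained-chromosome features as one
group), and per-chromosome (each chromosome against all others, no
multiple-testing correction across chromosomes — each panel is read as its
own test). The reported dosage expectation is log2(c/2).

## Integration

Deregulated miRNAs are joined to validated interaction records. "Total
interactions" counts one record per evidence entry after load-time
deduplication of exact (miRNA, target, tier) triples; "unique" counts
distinct target genes. The inverse-expression filter keeps pairs where
**both** members are deregulated and their calls have opposite signs; each
pair is evaluated independently (no aggregation over multiple miRNAs
hitting one target — a deliberate simplification of the many-to-many
regulation). Protein concordance asks, per distinct (target, expected
direction), whether the protein log2FC passes the same +/-0.6 threshold in
the direction the miRNA predicts (down for targets of up-miRNAs and vice
versa); targets without protein measurements are excluded from the
denominator and reported. Evidence scope "strong" restricts every count to
functionally validated records and can only shrink them.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, and
only that:

* **Annotation** — features placed on chromosomes 1–22, X proportionally
  to physical chromosome length; positions are uniform and used only for
  ordering; a configurable fraction of miRNAs is annotated with a host
  gene on the same chromosome (annotation only, no expression coupling).
* **Counts** — NB with per-feature-type dispersion (default phi = 0.05 for
  both assays), log-normal baseline means (median 100, log-sd 1 by
  default), and log-uniform size factors in [0.7, 1.4]. On a chromosome
  with copy number c, mRNA means scale by c/2 and miRNA means by (c/2)^alpha;
  the compensation exponent alpha is phenomenological — the data this
  emulates show miRNAs often failing to scale with copy number, and alpha
  makes that a tunable truth rather than a hard-coded behaviour. Copy
  number 0 silences a feature regardless of alpha.
* **Planted effects** — a fraction of features per type (default 10% at
  |log2FC| = 1, random sign) carries an extra differential effect, so
  sensitivity and FDR are measurable against known truth.
* **Interactions** — each (miRNA, mRNA) pair is reported with a configured
  density; a planted causal subset (always emitted, strong tier) links
  up-regulated planted miRNAs to otherwise unaffected mRNAs, whose means
  are repressed by 2^(-beta * delta) in aneuploid samples, delta being the
  miRNA's true log2FC.
* **Protein** — the mRNA truth plus Gaussian noise (sd 0.2 by default)
  minus an extra 0.5 log2 units of repression for planted targets,
  mimicking post-transcriptional reinforcement.
* **Determinism** — every operation draws from its own numpy stream
  derived from the single master seed, so standalone calls and pipeline
  runs produce identical bytes.

What the generator does **not** emulate — and therefore what passing tests
do not certify about real data: GC/length biases, batch effects beyond a
replicate label, isomiRs and miRNA processing, sub-chromosomal copy-number
segments, correlated co-regulation beyond the planted pairs, and the
many-to-many structure of real miRNA targeting. Conclusions about real
datasets still require the usual diagnostic checks.

## Study-condition problem sizes

The calibration and recovery analyses (tests and `scripts/acceptance.py`)
use: 5,000 features with 3 vs 3 paired replicates and 20 seeds for null
calibration; planted |log2FC| = 1 on 10% of 5,000 features at phi = 0.05
and means near 100 (baseline log-sd 0.25) over 10 seeds for effect
recovery; trisomy of chromosome 5 (~300 features at genome-proportional
weights) over 10 seeds for dosage recovery; and 200 miRNAs x 2,000 mRNAs
with 50 causal pairs at |log2FC| = 2, beta = 1 for pair recovery.

A note on attainable sensitivity: at means near 100 with phi = 0.05 and
three replicates per condition, the Wald standard error of the log2FC is
sqrt(2 * (1/100 + 0.05) / 3) / ln 2 ≈ 0.29. At the BH(0.05) operating
point this caps sensitivity for |log2FC| = 1 near 0.71 for *any*
correctly calibrated caller (an idealized caller given the exact standard
error reaches 0.73 in simulation); the pipeline measures ~0.68 with
estimated dispersions. Larger counts, smaller dispersion or more
replicates are the only honest routes to higher sensitivity at a
controlled FDR.

## Clustering and report

Log2FC profiles (miRNA x cell line) are ordered by agglomerative
hierarchical clustering with Euclidean distance and average linkage
(configurable; average is the common heatmap default — the choice was
open). Leaf order is deterministic (ties broken by input index). Missing
values are imputed as 0 with a logged warning; matrices with fewer than
two rows keep identity order. Rendering is out of scope: the pipeline
exports the ordered matrix so any plotter can draw the heatmap. The
pipeline writes per-line DE, dosage and pair tables as TSV, a run log, and
a single `summary.json` whose percentages always equal
round(100·k/n, 1) recomputed from their own printed numerator and
denominator fields.
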