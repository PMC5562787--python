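# Methods

This note documents the statistical procedures implemented in `leafsen`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions at the edges.

## Design and notation

The experiment is a two-leaf (flag leaf FL, second leaf SL), six-time-point
(4, 12, 20, 28, 36, 44 days after heading), three-replicate RNA-seq count
matrix: 36 libraries over genes. All statistics operate on the normalized
log2 abundance tensor `gene × leaf × time × replicate`. Time is always
carried in DAH units, never ranks, so integrals use the real 8-day spacing.

## Normalization

Counts are scaled to CPM with trimmed-mean-of-M-values (TMM) factors
(log-ratio trim 0.30, abundance trim 0.05, genes with a zero in either
sample excluded, factors normalized to geometric mean 1; the reference
library is the one whose upper-quartile abundance is closest to the mean).
The implementation reproduces the canonical formulation exactly (the test
suite holds an independent literal transcription of the formula; agreement
to 1e-10). Quantile normalization then forces every library's log2(CPM+1)
distribution onto the across-library mean of order statistics; tied values
receive the mean of the target values at the tied rank positions, so the
map is well defined on count-derived data and idempotent. Normalization is
applied jointly across all 36 libraries of both leaves.

The expressed-gene filter keeps a gene whose replicate-mean CPM exceeds 1
at ≥ 1 (leaf, time) combination. The filter intent is "drop unexpressed
genes"; it is applied to CPM because within-gene length normalization is
out of scope, and a per-replicate variant is available in config
(`expression_filter_scope`).

## SAG detection

Per leaf and gene:

- **Reproducibility.** Each replicate trajectory is smoothed with a
  Savitzky–Golay filter (order 2, frame 5). On a six-point series the two
  edge points cannot sit at a window center; they are filled by fitting
  the order-2 polynomial to the nearest five points and evaluating at the
  edge, the convention under which exact quadratics pass through the
  filter unchanged. The median of the three pairwise Pearson correlations
  between smoothed replicates is the reproducibility score. A constant
  smoothed profile makes the correlation undefined; such genes fail the
  filter, since a constant trajectory carries no age signal.
- **Cutoff.** The operative cutoff is the 95th percentile of a permutation
  null, floored to one decimal. The null permutes the time columns of each
  replicate's gene × time matrix independently (one permutation per
  replicate per round, shared by all genes), re-smooths and recomputes the
  per-gene median pairwise correlation, pooling 100 rounds into one
  empirical distribution. Smoothing makes neighboring points strongly
  dependent, which is why the null 95th percentile is high (≈ 0.7 — the
  smoothed-profile correlation of pure noise is far from zero) and why a
  naive parametric correlation threshold would be badly miscalibrated. A
  fixed cutoff (default 0.7) can be supplied instead
  (`pcc_cutoff_mode: fixed`).
- **Significance.** One-way fixed-effects ANOVA across the six time
  points on the raw (unsmoothed) log2 values — smoothing is used only for
  the reproducibility score, switchable via `anova_on_smoothed`. The
  per-gene p-values are Bonferroni-adjusted across all genes entering the
  analysis (the expressed set): the SAG definition consumes a single
  per-gene p, so the correction is across genes rather than across
  post-hoc time contrasts. A table with no variance at all is defined to
  have p = 1.
- **Effect size.** max over time of |mean log2 at t − mean log2 at 4 DAH
  of the same leaf| ≥ 1. The baseline is each leaf's own first time point
  (config-switchable to the FL 4 DAH baseline used for display purposes).

A gene is a SAG when all three conditions hold; the overall SAG set is the
FL ∪ SL union.

## Shared vs differential classification

For each SAG and time point, the FL−SL contrast is median(FL replicates) −
median(SL replicates) of log2 abundance, tested with a two-sided
pooled-variance t-test on the 3-vs-3 values (pooled rather than Welch:
with n = 3 per group the Welch degrees of freedom are unstable;
`t_equal_var` switches). Per-time-point t-tests are not multiplicity
corrected — the classification rule consumes raw p < 0.05 per point.

- **Shared**: |Δ| < 0.58 (= log2 1.5) at all six points. The Shared rule
  always uses 0.58 regardless of the criterion in force.
- **Differential (Criteria c)**: ≥ m time points where simultaneously
  |Δ| ≥ f and p < 0.05, with (f, m) = (0.58, 1), (0.58, 2), (0.58, 3),
  (1.0, 1), (1.0, 2) for Criteria 1–5. The ladder is nested by
  construction: Diff(5) ⊆ Diff(4) ⊆ Diff(1) and Diff(3) ⊆ Diff(2) ⊆
  Diff(1).
- **Neither**: large but never-significant differences.

Degenerate variance: equal means give p = 1, unequal means with zero
pooled variance give p = 0.

Direction of a differential gene is the sign of [mean log2 over 28–44 DAH
− mean over 4–20 DAH], averaged over leaves; an exactly zero trend breaks
to "down". This realizes "up/down-regulated during grain filling" for
monotone and offset archetypes alike.

**Hotelling-T² alternative.** The multivariate route tests the
6-dimensional FL−SL mean-profile difference: T² = (n₁n₂/(n₁+n₂)) dᵀΣ̂⁻¹d.
With n = 3 replicates a per-gene 6×6 covariance is singular, so Σ̂ is the
within-group covariance pooled across all genes and both leaves, shrunk
toward its diagonal with weight 0.5 (`hotelling_ridge`) plus a 1e-10 ridge
floor — a moderated covariance in the spirit of multivariate time-course
statistics; the permutation p-values make the exact shrinkage weight
secondary. The null permutes the time columns of every replicate matrix of
both leaves per round, recomputes Σ̂ and the statistic (1000 rounds), and
the one-sided empirical p uses the add-one correction
p = (1 + #{T²_null ≥ T²_obs}) / (1 + n_perm), so the smallest attainable p
is 1/1001. Permutations are shared across genes per round (the same
column-permutation scheme as the reproducibility null); marginal p-values
are exactly uniform under the null, at the cost of weak cross-gene
dependence that is irrelevant at the calibration tolerances tested.

## Pattern clustering

Correlation-similarity k-means is realized as row standardization followed
by Euclidean k-means: for zero-mean unit-variance rows, squared Euclidean
distance is 2(1−r), a monotone transform of correlation distance, which
keeps the standard centroid update valid. k = 30 per track, best of 20
restarts by within-cluster sum of squares, empty clusters re-seeded from
the farthest points (the scikit-learn behavior). Features: shared track —
the 12-dimensional (FL ⧺ SL) log2 fold-change profile relative to the FL
4 DAH mean; differential track — that profile concatenated with the
6-dimensional FL−SL difference profile, equally weighted (the relative
weighting is exposed through the feature construction, not a config knob).

Clusters split into up/down by the sign of their mean fold-change
profile's maximum-magnitude excursion — robust for peaked, non-monotone
patterns where the late value is near baseline. Within each direction
stratum, cluster mean profiles merge by complete-linkage Euclidean
hierarchical clustering cut at the configured pattern counts (shared:
4 up + 3 down → SP1–7; differential: 10 up + 6 down → DP1–16). The
direction split counts are data-driven outputs; only the pattern counts
are config targets. Differential patterns merge once more — complete
linkage on pattern-level mean FL−SL difference profiles, cut at 5 — into
groups G1–5; a group is major when it holds more than
⌈0.10 × (number of differential genes)⌉ genes (3058 differential genes
give the bar of 306).

## Enrichment

The EASE score is the one-tailed hypergeometric upper tail with one list
hit removed: p = P(X ≥ k−1), X ~ Hypergeom(N, K, n); k = 0 or 1 gives
p = 1, and EASE p ≥ Fisher p always. A term is reported at EASE p ≤ 0.05
with ≥ 5 list hits (the hit-count reading of the "≥ 5 genes" filter;
switchable in config). The universe defaults to the expressed genes —
the conservative standard background — switchable to all annotated genes;
unannotated genes stay in the universe. No multiple-testing correction is
applied across terms for the pass flag; a Benjamini–Hochberg column is
emitted for information.

## Perturbation metrics and platform concordance

The FL−SL gap of a gene is the trapezoidal integral of the difference of
mean (not median) expression over 4–44 DAH; the panicle-removal effect is
(Diff_PR − Diff_Con)/Diff_Con, undefined (logged, reported missing) when
the control integral is 0. Platform concordance per gene: both platforms'
per-leaf mean profiles are smoothed as above; per method (Pearson,
Spearman, Kendall) and leaf the cross-platform correlation is computed;
each platform weighs a leaf by the area under its smoothed profile from
the zero baseline (floored at 0 — negative areas are possible on log
scales); the leaf's final weight is the geometric mean of its two platform
weights, normalized over leaves; per-method scores are the leaf-weighted
sums and the combined score their geometric mean. The geometric mean is
undefined for non-positive scores; the implementation returns
sign(min score) × geometric mean of |scores| and flags the result — a
documented convention for a case the original recipe does not address.

## Synthetic data

The generator plants archetypal log2 trajectories: flat genes; shared
up/down archetypes with early, gradual and peaked timing spanning 4 log2
units (~16-fold, the scale of strong senescence programs such as
collapsing photosynthesis transcripts or induced senescence markers); and
differential archetypes whose SL−FL offsets reach 1.5 log2 units with
|offset| ≥ 1 at ≥ 2 time points at early or middle stages, mirroring the
major difference-group shapes. Sign convention, stated once and tested
everywhere: `offset_profile` is SL minus FL, so downstream FL−SL
differences equal −offset. Counts are negative binomial with
variance μ + φμ² (φ = 0.05 by default; φ → 0 is an exact deterministic
limit used by the analytic tests), means scaled so each library totals its
nominal size (40 million, with deliberate ±30 % library imbalance to
exercise TMM), and per-gene baselines drawn from a wide log2-normal
(sd 3.0) resembling real abundance distributions. The default study mix is
2000 genes: 40 % flat, 30 % shared, 30 % differential.

What the generator does *not* emulate: transcript-length effects, batch
effects beyond library size, correlated genes, dropout, or a realistic
(~40 000-gene) transcriptome in which regulated genes are a small
minority. The last point matters: quantile normalization assumes roughly
comparable distributions across libraries, and with 60 % of a 2000-gene
universe moving several log2 units the across-time distribution shape
genuinely changes, so the quantile step compresses planted amplitudes
(~4 → ~3.4 recovered) and bleeds small spurious trends into flat genes.
This is a property of applying the normalization to a small, signal-dense
universe, not a bug; passing recovery tests therefore demonstrate
robustness to it, and calibration (false-call) claims are asserted on
all-flat data where the normalization assumptions hold exactly.

Planted-truth labels: a gene is a true SAG in a leaf when its noiseless
profile satisfies the pipeline's own effect-size rule (max |log2FC| ≥ 1
from the leaf's 4 DAH level); differential truth is archetype class
membership. The planted annotation term draws its genes with configurable
odds from a chosen class (odds 1 = null draw, odds ∞ = subset of the
class). The panicle-removal condition re-draws counts with per-archetype
log2 shifts: FL-high classes shift FL down by the full offset (the gap
closes, relative change → −1), a hormone-like class widens its gap by
half the offset (relative change → +0.5), and a transport-like class is
untouched (relative change ≈ 0) — the qualitative directionality of a
sink-removal experiment. qPCR cycle thresholds are an affine transform of
the noiseless log2 profile plus Gaussian cycle noise (default sd 0.25)
with a constant-in-expectation reference gene.

## Numerical conventions and reproducibility

Problem sizes in the shipped study and acceptance runs: 2000 genes,
10 seeds for recovery, 100 permutation rounds for the reproducibility
null, 1000 for the Hotelling null — sizes at which every quantity is
stable to the tolerances asserted. A single top-level seed fans out to
all stochastic stages through independent derived streams
(`config.stage_seed`), so stages are individually reproducible and
mutually independent; identical config + seed yields byte-identical
output tables. Ties in quantile normalization average the tied rank
positions; k-means ties are resolved by the seeded restart with the best
inertia; an exactly zero direction trend breaks to "down" (logged).

## Known limitations

- The Hotelling route reuses one gene-shared shrunken covariance; genes
  with atypical autocorrelation structure are mis-calibrated relative to
  a per-gene covariance (unattainable at n = 3).
- Bonferroni across genes is deliberately conservative; genuinely weak
  (< ~8-fold) senescence trajectories are under-called at 3 replicates
  and dispersion 0.05, which the recovery metrics reflect.
- Assignment of genes outside the original differential set to existing
  groups (needed when comparing classifiers) uses nearest group-mean
  difference profiles — a documented convention, not a published
  procedure.
- The funnel utility tracks set membership only; it does not model
  uncertainty in upstream calls.
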