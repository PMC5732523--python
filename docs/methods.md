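# Methods

## Scope and data model

The package implements a tumor/normal methylation-biomarker workflow over
two kinds of input: array-style beta-value matrices (CpG × sample fractions
in [0, 1], joined to a 450K-manifest-like annotation of probe id, chromosome,
1-based hg19-style position, gene, relation to CpG island, SNP-in-primer and
prior-gene flags) and targeted bisulfite-sequencing count tables (per sample
and CpG: methylated/total reads, plus non-CpG cytosine tallies for
conversion estimation). All in-memory coordinates are 1-based inclusive; BED
export is 0-based half-open. Missing beta values are NaN, never 0, because 0
is a valid methylation fraction. CpG sites are strand-collapsed upstream;
strand is not tracked.

## Block construction and differential statistics

A methylation block is k = 6 CpGs consecutive in manifest genomic order on
one chromosome (windows never span chromosomes), sliding one CpG per step,
retained iff last − first position < 1000 bp (strict, reflecting the short
range of methylation co-regulation). Blocks therefore overlap by design.

Per feature (CpG, or per-sample block mean over the block's non-missing
CpGs) the statistics are:

- McaM, McoM — mean methylation fraction of cases and controls, missing
  values excluded per feature;
- Diff = McaM − McoM;
- fold change = (McaM + ε)/(McoM + ε) with ε = 10⁻³. The pseudocount keeps
  the ratio defined when McoM = 0 while leaving "FC > 2" semantics intact at
  methylation scale. Swapping labels maps FC to exactly 1/FC.
- two-sided Wilcoxon rank-sum P: exact null by enumeration when both group
  sizes ≤ 10 and no ties; otherwise normal approximation with midranks,
  tie-corrected variance and continuity correction (delegated to
  `scipy.stats.mannwhitneyu`; an exhaustive rank-assignment oracle in the
  test suite checks the exact path). If all values are tied, P = 1.
- Benjamini–Hochberg q-values (`statsmodels`), with two separate FDR
  families: all blocks form one family, all CpGs another.

Whether the block statistic should be applied to per-sample block means or
to pooled CpG values is genuinely open; per-sample means were chosen (a
block mean is one number per sample, matching how region means are used
downstream), and the choice is isolated in `block_stats`.

## The filter cascade

Stages run in order with strict inequalities exactly as configured
(defaults: stage 1 blocks McaM > 0.40, McoM < 0.20, FDR < 0.01, FC > 2;
stage 2 CpGs McaM > 0.25, McoM < 0.20, Diff > 0.15, FC > 2, FDR < 0.01;
stage 3 validation McaM > 0.15, McoM < 0.15, Diff > 0.10, FC > 2, raw
P < 0.05 — the validation set is small, so raw P rather than FDR). The
blood filter keeps a CpG only if its mean beta is ≤ `blood_mean_max`
(default 0.10, configurable — "very low in blood" needs an explicit
operational cutoff) in *every* blood reference dataset; probes absent from
a blood dataset are retained there with a warning. The annotation stage
keeps island/shore CpGs (`Island`, `N_Shore`, `S_Shore` — shelves and open
sea are "far from the islands") without primer SNPs or previously studied
genes; the literature exclusion is an input flag, not a computation.

Candidate regions are the stage-1 surviving blocks that still contain at
least one fully surviving CpG, identified by their span `chrom:start-end`.
Primer difficulty is w₁·|GC − 0.5| + w₂·max(0, longest T-or-A run − 4) +
w₃·SNP count with default weights (1, 0.25, 1); the functional form is the
package's own (only the three components are given by the underlying
method), weights are exposed in config, and the score is monotone in each
component's deviation. Ns count in neither GC numerator nor denominator.
Ranking is ascending difficulty with deterministic (chromosome, start)
tie-breaks; the top 5 are selected.

## Targeted-BS QC and region means

Conversion rate = converted non-CpG C / total non-CpG C (non-CpG cytosines
are assumed unmethylated). QC passes run in a fixed order — conversion
(< 0.98 removed) → CpG (mean coverage < 20× or missing rate > 0.20) →
sample (missing rate > 0.30) — because samples are filtered on conversion
first and on missingness last. A call is missing iff its total read count
is zero or the record is absent. Mean coverage is computed over non-missing
calls among conversion-passing samples; defining the CpG missing-rate
denominator over conversion-passing samples (rather than the final sample
set) resolves a circularity the ordered passes would otherwise have. Each
removed entity carries exactly one primary reason (coverage checked before
missingness). QC is idempotent: re-running it on its own output removes
nothing.

Region methylation per sample is the unweighted mean of per-CpG fractions
mᵢ/tᵢ over the region's non-missing CpGs (missing if all are missing);
coverage-weighted pooling is available as a toggle but is not the default,
since the region summary is meant to average *methylation status*, not
reads.

## Diagnostic models

Logistic models are unadjusted maximum-likelihood fits (statsmodels) on
methylation fractions; odds ratios are per unit (0 → 1) change of the
fraction and reported on both natural-log and log₁₀ scales with Wald 95%
CIs, because printed log₁₀(OR) values of ~3 are only consistent with
per-unit-fraction effects. Complete separation is detected and flagged on
the returned fit instead of silently diverging. AUC is the rank statistic
P(score_case > score_control) + ½·P(tie). The operating point maximizes
Youden's J over observed scores, ties broken toward higher specificity; a
fixed 0.5-probability cut is available in config since no thresholding rule
is canonical. Univariate/panel sensitivity and specificity are
resubstitution values; the CV suite provides the generalization estimates —
mirroring the two ways such results are usually presented.

The eight model families are logistic regression, random forest, RBF-SVM,
Gaussian naive Bayes, a single-hidden-layer (size 5) neural network, LDA,
mixture discriminant analysis and flexible discriminant analysis.
Hyperparameters follow the implementing library's defaults with fixed
seeds (RF 100 trees, MLP 200 iterations — scikit-learn defaults), pinned
in `ModelConfig`. MDA and FDA have no scikit-learn implementation and are
provided as small estimators: MDA fits a per-class Gaussian mixture (3
subclasses, tied covariance within class) and classifies by posterior; FDA
is LDA on a standardized degree-2 polynomial basis (the optimal-scoring
view — degree 1 reduces exactly to LDA). Cross-validation uses stratified
random fold splits drawn once per replication and shared across models;
sensitivity/specificity/accuracy are computed at each model's default
decision cut on train and held-out folds and averaged over folds ×
replications (fold-level means, not pooled predictions). Everything is
seeded; identical seeds give identical summaries. The default replication
count is 1000; scaled-down runs simply pass a smaller `reps`.

Subgroup analyses partition the evaluable samples by age (below/at-or-above
the median — with distinct ages the groups differ by at most one), sex,
smoking or alcohol, optionally composed with a restriction mask (e.g.
male-only); each subgroup gets per-region univariate results and the
combined five-region AUC, and a subgroup missing either class is reported
as not evaluable. Tumor/normal pairing is carried in metadata but models
treat samples as independent and unadjusted — a documented limitation
matching the unadjusted design being emulated.

## The synthetic-cohort generator

The generator's defaults are the emulated study conditions: discovery
84/16, validation 4/8, PBMC 111, PBL 527, a universe of 5000 background
CpGs plus 20 planted 6-CpG blocks (20–60 bp spacing, spans ≪ 1000 bp,
island/shore annotation, no SNP or prior-gene flags), and 94 BS pairs.
Background CpG spacing mixes wide gaps with island-like tight clusters so
that background windows do form blocks and stage 1 has a real null family.

Array betas are Beta(mφ, (1−m)φ) with φ = 30. Planted means: cases 0.45,
tissue controls 0.15, blood 0.05. The *validation* cohort's planted control
mean defaults to 0.10: the emulated validation cohort's control methylation
at the selected sites (0.07–0.12) sits below the discovery cohort's
(0.09–0.20), and a control mean exactly at the stage-3 cutoff 0.15 would
make `McoM < 0.15` a coin flip for every planted CpG by construction.
Background CpGs draw a per-CpG baseline (Beta around 0.12, clipped to
[0.02, 0.6]) shared by case, control and blood, so background case/control
values are exchangeable.

Targeted-BS counts: each sample–region mean is logistic-normal around the
group mean (tumor 0.45, normal 0.15 on the fraction scale) with a
per-sample effect shared across regions (SD 1.0 on the logit scale — a
global methylation propensity, which is what keeps the five regions from
being independent evidence) and an independent per sample–region effect
(SD 0.7); per-CpG fractions are Beta around the sample–region mean
(φ = 30). These two SDs were set by a variance decomposition reproducing
the discriminability typical of such panels (single-region AUC ≈ 0.8,
five-region panel AUC ≈ 0.85). Coverage is negative-binomial (mean 200,
dispersion 5 — targeted panels are overdispersed); calls go missing with
probability 0.02. Conversion rates are Uniform(0.985, 0.999), and
conversion failure is modelled mechanistically: unconverted unmethylated
cytosines read as methylated, so observed fraction = f + (1 − f)(1 − c) —
which is exactly why the < 98% filter matters. Three samples are seeded
with conversion 0.97 and two with 50% missingness to exercise QC.
Covariates honour the emulated marginals (male 69/94, smoking 58/94,
alcohol only among males at 34/69, age ≈ N(64, 9.6²) from the reported
median/IQR, rounded and clipped to [35, 90]); all females are non-alcohol
by construction. Region sequences for primer scoring are synthetic,
drawn per region from a stream keyed by the region's coordinates (GC
content Uniform(0.30, 0.70), SNP count Poisson(1)), so any caller
regenerates identical records from the same seed.

What the generator does *not* emulate: probe-level technical artifacts
(type I/II chemistry, batch effects), spatial correlation of background
CpGs beyond positional clustering, copy-number or purity variation, and
paired-sample correlation in the BS cohort beyond shared covariates.
Passing recovery tests therefore show that the cascade and models behave
correctly under the stated noise model, not that the thresholds are optimal
for any particular real cohort.

## Numerical and reproducibility choices

- Seeding: every stochastic path derives generators from
  `np.random.SeedSequence([seed, stream])`; CLI outputs are byte-identical
  across re-runs with the same seed (fixed `%.6g` float formatting).
- Vectorised Mann–Whitney is used only where both groups are > 10 and
  complete (always the asymptotic regime); otherwise the per-feature path
  applies the exact rule.
- Degenerate inputs: all-tied features give P = 1; a group entirely missing
  is an error; empty p-vectors, single-class labels, regions with no
  surviving CpGs, k > candidate count all raise instead of guessing.
- Problem sizes: the acceptance script runs the full default design once
  and the CV suite at 50 replications; the test suite uses 10 seeds for
  cascade recovery, 200 logistic-coverage simulations and 200 CV
  replications spread over 10 independent label shuffles.

## Known limitations

- The cascade's printed funnel counts depend on the synthetic design and
  are not comparable to any real cohort's counts.
- Stage-3 uses raw P (small validation set); if the validation cohort were
  large this would be anti-conservative.
- MDA/FDA are faithful-in-spirit small implementations, not ports of the R
  `mda` package; their decision boundaries can differ in detail.
- The logistic models ignore pairing; a conditional-logistic variant would
  be the natural extension.
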