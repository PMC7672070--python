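# Methods

## Overview

The pipeline estimates, for each subject, the difference δ between the age
predicted from a 3D structural volume and the chronological age, then treats
δ as an exposure: which phenotypes associate with it, which brain regions
drive it, and whether selected associations are causal. Each stage is a
standard method from the brain-age literature; the package's contribution is
a coherent, fully seeded implementation in which every stage can be
validated by parameter recovery on simulated cohorts.

## Age regression model

The regressor is a compact 3D residual CNN: a strided convolutional stem,
residual stages (two 3×3×3 convolutions per block with batch normalisation
and ReLU, a 1×1×1 strided projection on the skip path when resolution or
width changes), stride-2 downsampling between stages, global average pooling
and a linear head. Training minimises mean squared error with Adam
(lr 10⁻³, β = (0.9, 0.999)); the parameters with the best validation MAE
across epochs are retained.

The network and its gradients are implemented directly in NumPy.
Convolutions use `sliding_window_view` plus `einsum`; backward passes are
hand-derived and verified against central finite differences in float64 by
the test suite (relative error < 10⁻⁵ per coordinate, with a floored
denominator because a convolution bias feeding a batch-norm layer is an
exact null direction). This keeps the dependency footprint to the scientific
Python stack while remaining fast enough to train desk-scale cohorts (≈ 35 s
for 12 epochs on 280 volumes of 32³ on one CPU).

Defaults (`ModelConfig`): channels (4, 8, 16), one residual block per stage,
stem stride 2, batch size 16, 12 epochs. Inputs are z-scored per volume
(disable with `normalize_input=False`); targets are centred on the training
mean age, stored as a constant output offset, because a randomly initialised
network outputs values near zero and Adam would otherwise spend most of the
budget moving the head bias by ~60 years. With `n_epochs=0` the model is
returned untouched. Any input grid whose dimensions are at least the total
downsampling factor (stem stride × 2^(stages−1), 8 by default) is accepted,
including 182×218×182.

## Bias correction

Raw CNN predictions regress toward the training-cohort mean age. The
correction fits ordinary least squares ŷ_raw ≈ α + β·y on the **training
split only** and inverts it: ŷ = (ŷ_raw − α)/β. This makes a
perfect-after-correction predictor exactly unbiased and is the common
convention; the alternative of subtracting the fitted residual trend
(ŷ = ŷ_raw − (α + β·y) + y) is available via `BiasCorrection(mode="residual")`.
Both agree exactly on noiseless affine data.

A caveat quantified during design: the fitted (α̂, β̂) carry sampling error of
order σ/(sd(y)·√n_train), which induces a *true* residual slope of δ on age
in any downstream cohort. When the correction is fitted on a training split
no larger than the evaluation split, a slope t-test on fresh data rejects at
≈ 17% instead of 5% — not a bug but a property of plug-in corrections. The
package therefore expects the correction to come from a large training
cohort (the tests use n = 3,000 against 300-subject validation splits, at
which point the test is calibrated).

## Synthetic cohorts

`generate_atlas` partitions a central ellipsoid into R contiguous regions by
nearest-seed (Voronoi) assignment of foreground voxels to R uniformly drawn
seed voxels — disjoint, nonempty, roughly compact parcels by construction.
R defaults to 20 at desk scale; real whole-brain parcellations are larger
(order 10²) and anatomically shaped, which this makes no attempt to mimic.

`generate_volumes` plants the age signal as a linear shift of region-mean
intensity: inside each signal region the mean moves by `effect_size` ×
(brain age − age-range midpoint), where brain age = chronological age +
δ_true and δ_true ~ N(0, `delta_sd`). The default `delta_sd` = 3.72 years
matches the dispersion typically reported for brain-age gaps in large
cohorts; the default cohort draws ages uniformly on 45–80 years, uses
effect size 1 intensity unit/year against unit-variance voxel noise, and
region baselines on 50–150 arbitrary units. The linear region-mean
mechanism is deliberately the simplest signal both a CNN and a closed-form
OLS oracle can detect; the simulator does not model anatomy, tissue
classes, scanner noise spectra, motion, or misalignment, so passing tests
demonstrate correctness of the machinery, not real-data performance.

`generate_traits` links traits to z = δ_true/sd(δ_true): continuous traits
are baseline + β·z + N(0, σ); binary traits are Bernoulli with logit =
logit(prevalence) + log-OR·z; ordinal traits come from a cumulative-logit
model with evenly spaced cutpoints. Missingness is completely at random.
A binary trait whose realised minority class has fewer than two members is
rejected as degenerate rather than passed to the scan.

`generate_mr_summary` draws instrument strengths γ_j ~ U(0.03, 0.15),
exposure effects γ_j + N(0, se_x) and outcome effects θ·γ_j + α_j +
N(0, se_y), with α_j = 0 for valid instruments and α_j ~ N(pleiotropy mean,
sd) for the invalid fraction. The default se_x = 0.004 keeps every
instrument's |z| ≥ 7.5 — simulated instruments should look like
genome-wide-significant GWAS hits, and precisely estimated exposure effects
are also the NOME assumption under which MR-Egger is unbiased (with noisier
instruments Egger exhibits its textbook regression-dilution attenuation).
A configurable fraction of variants is emitted in the opposite allele
orientation (and optionally as palindromic A/T / C/G pairs) so that
harmonisation is exercised end to end.

All generators take one explicit seed and are bit-reproducible; there is no
global RNG state.

## Cohort split

`make_split` assigns subjects to training / validation / healthy-test /
general-test sets at fractions defaulting to 0.1434/0.1853/0.0962/0.5751
(the proportions of a 3,067 / 3,962 / 2,057 / 12,296 split of 21,382
subjects). Unhealthy subjects may only enter the general-test set; the
three healthy-only sets are filled from the shuffled healthy pool and the
remainder joins the general set. The simulator exposes a binary healthy
flag; it does not attempt to reproduce any registry-specific (e.g. ICD
code) stratification logic.

## Region permutation importance

Importance is cross-subject patch exchange at fixed coordinates: volumes
share a template grid, so replacing subject i's voxels inside a region with
subject π(i)'s (π a random bijection, drawn uniformly excluding the
identity) preserves the region's marginal intensity distribution while
destroying its subject-specific information. Within-subject voxel shuffling
is deliberately not offered: it would destroy intensity statistics the
method is designed to preserve. ΔMAE = mean over `n_repeats` permutations
(default 10) of the permuted MAE minus the baseline MAE; values can be
negative by sampling noise and are reported as computed. `rank_regions`
sorts by ΔMAE descending (ties broken by ascending region id) and flags
regions above a reporting threshold of 0.10 years; the threshold is a
descriptive cut, not a test.

## PheWAS

The exposure is standardised once, by the δ standard deviation of the
analysed cohort, so effects are per SD of δ and invariant to rescaling.
Covariates are age, sex, and centre as fixed-effect dummies. Fits go
through statsmodels: OLS (continuous), Logit (binary, reported as odds
ratios), OrderedModel with a logit link (ordinal, reported as an OR under
the proportional-odds convention — ordered-trait handling varies between
scan tools, and this is the choice made here). Rows with missing values are
excluded per trait, with exact n_used/n_missing accounting; traits that are
underpowered (n < 10), degenerate, or fail to converge are reported with a
status string, never silently dropped. Continuous traits are analysed
untransformed; a rank-based inverse-normal transform is a reasonable
alternative convention and can be applied upstream by the caller.

Bonferroni takes the number of tests as an explicit argument — for 1,410
tests at α = 0.05 the threshold is 3.55 × 10⁻⁵ (a published analysis of
"1,410 traits" prints 2.35 × 10⁻⁵, which corresponds to ≈ 2,128 tests; the
implementation does the arithmetic and leaves the test count to the user).
The Benjamini–Hochberg step-up rule is implemented directly (sort, largest
k with p(k) ≤ kq/m) and cross-checked against
`statsmodels.stats.multitest.multipletests` on random p-vectors in the
tests; NaN p-values (skipped traits) are never rejected but still count
toward m, the conservative choice.

## Mendelian randomisation

Harmonisation keeps variants present in both tables, flips the outcome beta
(and complements its allele frequency) when the alleles are swapped, resolves
opposite-strand reports via nucleotide complements, and drops incompatible
pairs. Palindromic variants are dropped by default; `palindromic="infer"`
retains them when both allele frequencies are informative (|eaf − 0.5| >
0.08, configurable) and uses frequency agreement to orient them. Every
decision is recorded in an audit log.

LD clumping is greedy over a user-supplied symmetric r² matrix (no reference
panel is bundled): repeatedly keep the remaining variant with the smallest
exposure p-value (variant-id tiebreak) and drop everything with r² ≥ 0.1
(default) against it.

Estimators, all authored here and checked against closed-form oracles:

* **IVW** (fixed-effect): estimate Σwⱼβ̂xⱼβ̂yⱼ/Σwⱼβ̂²xⱼ with wⱼ = 1/σ²yⱼ;
  SE = (Σβ̂²xⱼ/σ²yⱼ)^(−1/2); normal p-values. Cochran's Q over Wald ratios
  with n−1 df.
* **MR-Egger**: WLS of β̂y on β̂x with intercept, weights 1/σ²y, after
  orienting all β̂x ≥ 0; t-based inference with n−2 df and estimated scale;
  the intercept estimates average directional pleiotropy. Residual Q with
  n−2 df.
* **Weighted median**: Wald ratios weighted by β̂²x/σ²y (first-order delta
  method; the second-order term is omitted by default), estimate
  interpolated at cumulative weight 0.5, SE from a seeded 1,000-draw
  parametric bootstrap, normal p-values.

`mr_suite` chains harmonise → clump → all three estimators, flags pleiotropy
at Egger-intercept p < 0.05 and heterogeneity at IVW Q p < 0.05, and
degrades gracefully (IVW + median with a warning) below 3 variants. Both
the Q statistic and its p-value are reported so either convention for
quoting heterogeneity can be checked.

A property worth knowing when interpreting the weighted median: under
*directional* pleiotropy carried by a fraction f < 0.5 of the weight, the
estimator targets the 0.5/(1−f) quantile of the valid ratio distribution,
so it is far less biased than IVW but not exactly unbiased at any finite
noise level; under balanced (zero-mean) pleiotropy it is unbiased. The test
suite checks exactly these two statements.

## Numerical and testing choices

* float32 network parameters (float64 for gradient checking); identity
  affines on all NIfTI output within a cohort.
* Desk-scale problem sizes used by the tests: 32³ grids, 400-subject
  cohorts, 20 regions with 2 signal regions, 1,000-trait null scans at
  n = 300, 5,000-subject trait-recovery scans, 30-instrument MR simulations
  with 200 Monte-Carlo replicates. These sizes make every recovery margin
  wide relative to its Monte-Carlo error while keeping the whole suite
  runnable on one CPU.
* Monte-Carlo assertions use 2 (means) or 3 (counts) standard-error bands
  computed from the replicates themselves; exact identities (permutation
  no-ops, single-instrument IVW, noiseless Egger, the BH step-up on a
  four-value example) are asserted exactly or at 10⁻⁸–10⁻¹⁰.

## Known limitations

* The simulator's age signal is linear in region-mean intensity; a CNN
  trained on it will not demonstrate sensitivity to texture or shape, and
  no claim transfers to real MRI without retraining and revalidation.
* Batch-norm running statistics come from small desk-scale batches; for
  very small training sets inference-mode predictions early in training can
  differ noticeably from training-mode behaviour.
* The PheWAS treats traits independently; correlated traits make Bonferroni
  conservative (the FDR path exists for exactly that reason).
* LD clumping requires the caller to supply the r² matrix; no genotype
  reference data ships with the package.
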