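# Methods

## Two-level stacked regression

The pipeline predicts a continuous per-subject score from K feature
channels (modalities). Level 1 fits each channel independently with
LASSO-PCR; level 2 re-learns the channels' predictions with a non-negative
LASSO. The design assumes channels carry partly shared, partly unique
response variance; the non-negative L1 meta-model is what removes the
shared (redundant) part.

### Level 1: LASSO-PCR

For a training matrix `X` (n × p), columns are centered (not variance
scaled — features within one channel share units, and scaling would distort
the principal axes) and decomposed by an economy SVD. All `min(n−1, p)`
numerically nonzero components are retained; truncating the basis would add
an undocumented filter on top of the L1 selection. The response is centered
by the training mean (which becomes the intercept) and regressed on the
component scores `Z = US` under the per-sample-scaled L1 objective
`(1/2n)‖y − Zβ‖² + α‖β‖₁` (scikit-learn's coordinate-descent convention; on
this scale duplicating every observation leaves the fit unchanged).
Component scores are *not* standardized before the L1 step, so the penalty
acts on the natural score scale — high-variance components are cheaper to
keep. This is a documented convention, not a mathematical necessity.

The penalty grid has 30 log-spaced values from the data-driven entry point
`α_max = max|Zᵀy|/n` down to `10⁻³·α_max`. Selection is by minimum mean CV
MSE over an inner k-fold (default k = 5, shuffled with a seeded RNG); no
one-standard-error rule. Ties prefer the stronger penalty. The PCA basis is
refit inside every inner fold — sharing the basis across folds would leak
held-out rows into the selection.

The inner pass doubles as the producer of out-of-fold (OOF) training
predictions: each row's prediction comes from the fold model that excluded
it, evaluated at the selected penalty; the final model is then refit on all
training rows at that penalty. Score-space coefficients are back-projected
to a feature-space weight map `ŵ = Vβ̂`, and `predict` is the affine map
`(X_new − x̄)ŵ + ȳ` — identical (to ~1e−15) to predicting through score
space.

### Level 2: non-negative LASSO

OOF prediction vectors are stacked as meta-features (one column per
channel, response units). They enter uncentered and unscaled so the
constraint `β ≥ 0` stays interpretable as channel weighting; the intercept
absorbs the response mean. Penalty selection mirrors level 1 (30-point
grid from the positive-correlation entry point, inner 5-fold CV). With
duplicated meta-columns the coordinate-descent tie-break follows fixed
column order, so an exact duplicate channel receives weight zero; only the
(unique) predictions are contractual, not the weight split.

Within one train/test split, the inner fold assignment is derived from the
split seed alone and shared by all channels, so identical channels produce
bitwise-identical meta-columns.

## Cross-validation and summaries

Monte Carlo cross-validation: default 100 random 70/30 partitions. Families
(twin pairs) are the sampling unit — whole families are shuffled and added
to the test side until it reaches `round(0.3·n)` subjects, so the test size
overshoots by at most one family and no family ever straddles a split.
Optional stratification bins families by quintiles of the group-mean
response and fills the test quota proportionally per bin; it is off by
default, matching the plain group-shuffle protocol.

Per-split R² (1 − SS_res/SS_tot; can be negative) and MAE are summarized by
the median and its percentile-bootstrap CI (1000 resamples, α = 0.05) — the
median because the sparse level-2 weights have point masses at zero.
Pairwise channel comparisons use the one-tailed Wilcoxon signed-rank test
(exact null for ≤ 25 informative pairs; zero differences dropped; an
all-tie comparison is degenerate and reported as p = 1 with a warning
rather than an exception) with the matched-pairs rank-biserial correlation
as effect size.

The stacking bonus is computed per split and summarized as a median:
`B_mean = R²_stacked − mean(R²_single)` is optimistic in the presence of
poor channels, so the conservative `B_best = R²_stacked − max(R²_single)`
is the headline variant.

## Confound handling

Two mechanisms, chosen by what the confounder is:

- **Neuroimaging confounder (intracranial volume).** Partialled out of the
  *response* by simple linear regression whose intercept and slope are
  estimated on the training rows only; train and test responses are both
  replaced by residuals under those train-fitted coefficients. One
  confounder only; several would be residualized sequentially and are not
  implemented.
- **Mediating demographics (age, sex, education).** Assembled as their own
  channel (sex one-hot with a dropped reference level, education as a
  numeric ordinal — the coding is a choice, and standardizing education
  instead would only rescale one coordinate of an L1 fit that is not
  scale-invariant; the default keeps interpretable units) and stacked like
  any imaging channel: if demographics carry the variance, the level-2 L1
  shrinks the imaging channels away by itself.

## Interpretation layer

Decoding weights of a backward model are not feature–response associations:
a feature can earn a large weight purely to cancel noise. Channels whose
median level-2 weight has a bootstrap CI excluding zero (`ci_low > 0`,
weights being non-negative) are refit on all observations — with the
penalty re-optimized by inner CV, since the fixed per-split penalties
belong to smaller training sets — and their weight maps transformed to
encoding patterns `A = Σ_X ŵ`. The response-variance factor of the general
transform is a scalar for a single response and is omitted; patterns are
therefore defined up to a positive scale, which the max-abs rescale to
[−1, 1] (zeros preserved exactly) then fixes. The covariance uses the n−1
denominator (irrelevant after rescaling) and is applied implicitly as
`X_cᵀ(X_c ŵ)/(n−1)`, never materializing the p × p matrix.

For link-type channels (vectorized connectomes), strength maps devectorize
the absolute loadings to the symmetric link matrix, keep the top 1 % of
links by absolute value (ties at the cut kept; the thresholding applies to
links *before* row-summation), and report row sums per region. Grouped
summaries average strictly-positive (or strictly-negative) loadings per
anatomical group; zeros count as neither sign, and a group with no loading
of the requested sign is reported absent.

Vectorization uses the row-major strictly-upper triangle (diagonal
excluded — the self-correlation of a z-transformed connectome is infinite);
the ordering is recorded so maps are reconstructable, and
vectorize/devectorize is an exact bijection on symmetric zero-diagonal
matrices.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, with
everything downstream testable against known truth:

- one shared latent trait `g` plus one unique latent `u_k` per channel, all
  standard normal; the response core is
  `y = a·g + Σ_k √(b_k)·u_k + √(1 − a² − Σ b_k)·ε`;
- channel matrices `X_k = √(s_k)·g p_kᵀ + u_k q_kᵀ + σ·E` with sparse
  generative loadings (default 10 % nonzero) so sparse recovery is
  meaningful;
- `s_k` (shared) and `b_k` (unique) are per-channel variance fractions of
  the response core. Because there is a single shared latent, its response
  share is taken as `max_k s_k` while each channel expresses it with
  amplitude `√s_k`; validity requires `max(s) + Σ b ≤ 1`;
- twin pairs (default 40 % of subjects, matching the roughly two-fifths of
  the motivating cohort with genotype-verified twin labels) draw their `g`
  from a bivariate normal with correlation 0.6; unique latents and noise
  are independent within pairs;
- metadata: intracranial volume ~ N(1.5, 0.15) litres, age 22–37, sex F/M,
  education 11–17 years. Confounder slopes act on centered values; response
  and feature shifts are exact linear functions of the planted confounder.
  Slopes default to zero (null confounding) so each study states its own;
  `realistic_confounders()` provides a preset in which demographics
  out-predict any single imaging channel, dominated by education.

What the generator does **not** emulate: realistic covariance structure
within a channel (features are conditionally independent given the
latents), non-Gaussian score distributions, heteroscedastic noise, site or
motion artifacts, and any spatial organization. Passing tests therefore
demonstrate the *machinery* — leakage-free selection, redundancy removal,
calibrated null behaviour — not performance on real imaging data, whose
effect sizes are far smaller than the defaults here.

## Problem sizes and numerics

Simulation-based checks use cohorts of 300–400 subjects, channels of
200–300 features and 25–50 Monte Carlo splits — large enough that the
bootstrap CIs separate the complementary, redundant and null regimes
cleanly, while a full study run stays in the tens of seconds on one core.
Degenerate inputs: a zero-variance confounder falls back to intercept-only
adjustment with a warning; an all-zero-variance channel is an error; an
empty penalty grid is an error; non-finite inputs are rejected at every
fitting surface. All randomness descends from one master seed through
spawned, independent streams (splits, per-split fold shuffles, bootstrap),
so extending a study never perturbs earlier results and reruns are
bit-identical.

## Known limitations

- Single response per run; no multi-response stacking.
- Level 1 offers no elastic-net/ridge variants and no classification mode.
- One neuroimaging confounder in the residualization step.
- The level-2 intercept is included (the protocol leaves this open; a
  centered-response reading makes it harmless).
- Bootstrap CIs treat splits as exchangeable; overlapping training sets
  across Monte Carlo splits make them optimistic as frequentist intervals —
  they are summaries of the split distribution, not tests.
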