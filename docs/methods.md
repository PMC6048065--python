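# Methods

## The diagnostic model

The diagnostic is PLS1 regression of a binary outcome (healthy control = 0,
case = 1) on a feature matrix that is centered and scaled to unit variance
per feature; the outcome is centered. NIPALS deflation yields the bilinear
decomposition `X = TPᵀ + ε_X`, `y = TBᵀ + ε_y` with mutually orthogonal
score columns; for a univariate outcome the weight vector has the closed
form `w = Xᵀy/‖Xᵀy‖`, so no inner iteration is required. Predictions for
new samples use the rotation matrix `R = W(PᵀW)⁻¹`. The residual terms play
no operational role beyond the MSEP decomposition below.

Raw PLS1 output is a real number; it is clipped to [0, 1] and read as an
"RA probability". The link function is a deliberate design choice: clipping
plus ensemble averaging reproduces the required 0–1 range without
introducing a calibration step, and member probabilities are averaged on
the probability scale, not the logit scale. Log-odds use a clamp of 1e−6
at the boundaries. Molecular remission is a strict threshold: probability
< 0.5.

The ensemble: the case/control cohort is split into 5 diagnosis-stratified
folds; each fold serves once as the held-out fifth, and the whole split is
repeated 3 times with fresh shuffles, giving 15 members. Every sample is
held out exactly 3 times. Stratification is our choice (it keeps the class
ratio constant per fold, which also keeps the permutation null centered);
the member count and split geometry are fixed by the design. Per member,
the component count l ∈ {1..10} maximizes the mean inner 10-fold CV Cohen's
kappa of 0.5-thresholded predictions; ties and undefined kappas resolve to
fewer components. Because PLS components are nested, one inner fit at the
maximal grid value covers the whole grid via cumulative partial
predictions.

The permutation null shuffles diagnosis labels and reruns the *entire*
fit, including component selection, recording mean held-out accuracy.

## Variable contributions

Evaluated per member on its own training fold, where the score matrix T is
defined without projection ambiguity:

- partial predictions `f_s(k) = ȳ + Σ_{i≤s} t_ki·b_i`, with `f_0` the
  intercept-only prediction;
- `MSEP_s = (1/n) Σ_k (f_s(k) − y_k)²`, so `MSEP_0` is the outcome variance
  around the training mean;
- `w_s = (MSEP_s − MSEP_{s−1}) / Σ_{i=1..l}(MSEP_i − MSEP_{i−1})` — the
  denominator telescopes to `MSEP_l − MSEP_0`, so the weights sum to 1.
  Components that *increase* MSEP get negative weights; we keep the signed
  values (an `absolute=True` flag is available);
- `g_i = (1/l) Σ_j p_ij·w_j`, `r_i = g_i / Σ_j g_j`, max-scaled to 100.

The loading index convention is: `p_ij` is the loading of feature i on
component j. Ensemble contributions are the arithmetic mean of member `r`
vectors; the member SD is the reported uncertainty. A downstream screen of
"importance > 50" is exposed as a threshold parameter (default 50).

## Differential analysis

Per-feature OLS with nuisance covariates (age for all layers, RIN
additionally for transcripts), moderated by empirical-Bayes variance
shrinkage: the prior (d₀, s₀²) is fitted by method of moments on the
log-variance scale (digamma/trigamma matching of a scaled
inverse-chi-square), posterior variances are `(d₀s₀² + d·s²)/(d₀+d)`, and
the moderated t uses d+d₀ degrees of freedom capped at the pooled residual
df. The test suite verifies exact agreement with Bioconductor limma's
eBayes on a shared fixture. Paired week contrasts put the subject in the
design as a blocking factor. q-values are Benjamini–Hochberg (π₀ = 1) — a
conservative, dependency-free stand-in for Storey's estimator; the
significance gate requires p < 0.05 AND q < 0.05, which the joint rule
dominates.

Trajectory testing fits a linear mixed model: cubic B-spline fixed effects
of week (default df = 3, boundary knots at the observed extremes, interior
knots at quantiles for df > 3) with a random intercept per subject, ML
estimation, and a likelihood-ratio test of all spline coefficients. With
exactly three distinct weeks the cubic basis plus intercept is rank
deficient (the cubic space restricted to three points is
three-dimensional); collinear columns are dropped by QR rank detection and
the LRT df adjusted accordingly.

## Residual molecular signatures

Stage 1 (consensus): significant in the same direction versus controls in
all three arms at week 0, among responders (n = 10 per arm). Stage 2
(residual): the consensus subset still passing both gates with unchanged
direction in all arms at week 24. "Same direction" means the sign of the
group coefficient, not a fold-change magnitude. Per-arm residual sets are
emitted alongside the all-arm intersection. Tightening either threshold
can only shrink a signature, and identical week-0/week-24 evidence
reproduces the consensus — both properties are tested.

## ssGSEA

Per sample: features are ranked (average ranks for ties), walked in
decreasing order; the in-set running ECDF weights each member by
rank^τ (τ = 0.25), the out-set running ECDF is uniform; the score is the
sum of the running differences (integrated deviation), with no further
normalization. Scores are therefore invariant to any strictly monotone
transform of a sample's values. Cell-type specificity standardizes scores
across reference cell-type columns, per signature (cells only, not cells
then genes — a documented choice where the convention was open).

## Cell-count attribution

Elastic net in the glmnet convention (α = L1/L2 mixing, λ = penalty);
default grids α ∈ {0, 0.1, …, 1} and a 50-point geometric λ path from the
smallest all-zero penalty, tuned by mean RMSE over 3 × 10-fold CV. Pure
ridge points (α = 0) are solved in closed form via SVD for the whole λ
path. The selected (nonzero-coefficient) cell variables are refitted by
OLS; the refit R² is the "variance explained" quantity. LMG importance
averages each regressor's sequential sum of squares over orderings:
exactly over the 2^p subset lattice for p ≤ 15, by ≥ 5000 Monte-Carlo
orderings beyond (averaging over *all* orderings is combinatorially
infeasible at 26 regressors; the exact/MC switch is the documented
resolution). Shares are nonnegative and sum to the refit R². The
goodness-of-fit p permutes the response and reruns the tuned workflow,
with add-one smoothing, so p ≥ 1/(n_perm+1). The shared-effect test is a
mixed model (score ~ diagnosis with a random intercept per cell type,
Wald p for the fixed effect).

## Preprocessing

Order: batch adjustment → covariate regression-out → feature filtering.
Batch effects are purely technical, so they are removed before any
coefficient estimation. Batch adjustment matches per-feature bridge
replicate means and SDs onto the reference batch (lowest id):
`x → (x − μ_b)/s_b + μ_ref`, with near-zero scale estimates guarded to 1.
This replaces empirical-Bayes batch correction by design — the bridge
replicates exist precisely to estimate the batch map, and the direct
estimator is deterministic and testable. When a bridge subject has copies
in several batches, the copy from the latest batch is kept.

Covariate models are fitted on training samples only, with the disease
label included in the design so nuisance estimates are not contaminated by
case/control differences; only the nuisance coefficients (age, gender,
RIN) are subtracted, and the same coefficients are reused verbatim on
held-out or treated samples.

Feature QC, in order: drop unmapped/multi-gene features; drop features
absent in > 1/3 of samples; collapse multiple features per gene when
pairwise correlation (Pearson, pairwise-complete, all QC-passing samples)
exceeds 0.3, keeping the highest-mean feature (ties → lexicographically
smallest id); drop the bottom 20% of interquartile ranges (computed over
all samples). Filtering is idempotent.

## The synthetic cohort generator

The generator emulates the statistical structure of a two-batch
case/control study with three longitudinal treatment arms, not any real
dataset. Defaults (chosen once, as study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| cohort | 45 RA / 35 HC; 3 arms × 10 responders × weeks {0, 4, 24} | design sizes of the emulated study |
| features per layer | 2000 | large enough for realistic multiplicity, small enough for desk-scale runs |
| planted disease features | 200, of which 50 treatment-resistant | resistant ⊂ disease by construction |
| disease shift | 2.0 × the feature's marginal SD (jitter U(0.9, 1.2)) | hallmark-level effects, consistent with near-perfect reported discrimination in this setting |
| cell types | 6 (neutrophil, monocyte, NK, CD4 T, CD8 T, B) | canonical leukocyte panel; neutrophil +1.0, monocyte +0.8, NK −0.8 SD disease shifts (left shift) |
| treatment decay (fraction of disease effect remaining at weeks 0/4/24) | MTX 1/0.70/0.35, IFX 1/0.45/0.12, TCZ 1/0.40/0.08 | biologics act faster and deeper than methotrexate |
| confounders | age (cases older), RIN (transcripts), 2 batches with location/scale distortions, 8 bridge replicates | exercises every preprocessing stage |

Effect sizes are expressed relative to each feature's *marginal* SD (noise
plus cell-mediated variance), so the planted standardized effect does not
depend on how strongly a feature tracks cell composition. Treatment scales
the direct disease shift of non-resistant features and the cell-level
disease shifts by the decay fraction; resistant features keep their full
shift at every week and additionally load on the three driver cell types
with signs matched to their direction. Cell counts are emitted both
absolute (`_a`) and relative to the total (`_r`). Presence flags are
Bernoulli with probability increasing in the feature's baseline level, so
the presence filter is exercisable. All randomness flows from one seed via
named SeedSequence substreams.

What the generator does **not** emulate: probe-level microarray
intensities, aptamer chemistry, flow-cytometry gating, count skewness and
mean-variance coupling of real transcriptomes, clinical index dynamics, or
inadequate responders. Passing tests therefore demonstrate correctness of
the *procedures* under a known generative model, not performance claims
about real cohorts.

## Numerical choices and degenerate inputs

- Constant features get unit scale inside PLS1; a constant outcome, a
  component count above rank(X), or an exhausted outcome residual raise.
- Undefined kappa (chance agreement 1) is treated as 0 in component
  selection.
- A zero total-MSEP change or a zero contribution sum raises rather than
  returning NaNs.
- Zero-variance rows refuse standardization; degenerate residuals after
  cell adjustment report an adjusted R² of exactly 0.
- Fisher odds ratios are conditional MLEs; infinite estimates are reported
  as a 1e12 sentinel. Stouffer inputs at 0/1 are clamped with a warning;
  input p-values are treated as two-sided with a separate direction sign
  (a `two_sided=False` switch accepts one-sided input).
- Permutation p-values use add-one smoothing and never report 0.

## Problem sizes in tests and the acceptance script

Unit tests run reduced cohorts (hundreds of features); the acceptance
suite and `scripts/acceptance.py` use the full 2000-feature design with a
50-permutation ensemble null, 10–20 cohort seeds for signature recovery,
99 permutations for the decomposition goodness-of-fit, and reduced
permutation counts with small tuning grids for the calibration studies —
sizes chosen to keep a complete run in the minutes range on one CPU while
leaving every statistical conclusion stable.

## Known limitations

- BH q-values are conservative relative to Storey's estimator when the
  null fraction is well below 1; signature sizes may shrink slightly.
- The LRT for spline fixed effects in mixed models relies on asymptotics;
  at very small subject counts it can drift anti-conservative.
- The ensemble's probability is uncalibrated by design (no Platt/isotonic
  step); only the 0.5 boundary and the ordering are interpreted.
- Multiclass outcomes, surrogate-variable adjustment, and
  deconvolution-style estimation of cell fractions from bulk profiles are
  out of scope.
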