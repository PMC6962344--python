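# Methods

## The classification scheme

`modfuse` implements a late-fusion ensemble for binary case–control
classification over M feature modalities. Per modality a classifier maps
a subject's feature vector to a signed decision value d (negative =
control, positive = patient, |d| = certainty). The ensemble prediction is
the sign of the weighted sum S = Σ w·d over the subject's *available*
modalities, with integer weights w ∈ {1, 2}. Missing modalities are
omitted from the sum; a subject therefore needs only one available
modality to be predicted, and no imputation step exists anywhere.

Everything that is learned — preprocessing parameters, classifier type,
the SVM cost C, the modality weights — is learned inside the training
fold of the outer leave-one-out loop. The outer loop holds out *all*
modalities of one subject at a time, so each subject is predicted exactly
once by a model that never saw any of its data.

### WeiRD

The weighted robust distance classifier stores the two class centroids
(per-feature means over training subjects of each class) and a
per-feature weight |t_f| from a pooled-variance two-sample t-test on the
training data. The decision value of a test vector x is

    d(x) = Σ_f |t_f| · ( |x_f − c_control,f| − |x_f − c_patient,f| ),

i.e. the difference of weighted Manhattan distances to the two
prototypes: positive when x is nearer the patient prototype. Features
with zero pooled variance get weight 0 — a feature constant within both
classes carries no evidence and must not vote. WeiRD has no tunable
hyperparameter.

Feature importances ("votes") are the per-feature contributions
|t_f|·(|x_f−c_ctr|−|x_f−c_pat|) signed by the sample's true class and
averaged over samples, so a positive importance means the feature pushed
decisions toward the correct class on average. By linearity the votes sum
to the mean class-aligned decision value.

### SVM

The second classifier is a soft-margin RBF-kernel SVM (libsvm through
scikit-learn). Only the cost parameter C is tuned, on the fixed grid
C = 2^x, x = −5 … 10 (16 candidates); the kernel width is held at
γ = 1/n_features so the search space is one-dimensional. SVM feature
importances are the dual-coefficient-weighted sum of support vectors,
Σ α_i y_i sv_i — a descriptive approximation only, since with an RBF
kernel the separating hyperplane lives in feature space, not input space.

Inside the nested loops the package fits the many small candidate SVMs
through scikit-learn's low-level libsvm binding on a per-fold precomputed
kernel matrix. This skips per-call input validation and is roughly 7×
faster; a test pins its decision values to the public `SVC` estimator for
both class orders, so the fast path is an implementation detail, not a
model variant.

## Preprocessing

Two per-feature transforms, both fit on training subjects only and then
applied frozen to held-out subjects:

- **Residualization** (only when covariates are supplied): each feature
  is replaced by its OLS residual against an intercept, age (continuous)
  and full-rank indicator contrasts for gender and site. Rank-deficient
  designs (e.g. a single site) fall back to the minimum-norm solution,
  which leaves residuals well-defined. A category level unseen at fit
  time raises — no extrapolation rule is defined.
- **Soft-normalization**: subtract the training median, divide by the
  training 1%–99% quantile range (linear-interpolation quantiles). The
  scale is guarded by ε = 10⁻¹² so constant features map to 0 instead of
  dividing by zero. The transform is exactly invariant under positive
  affine per-feature rescaling of the raw data.

By default both are re-fit inside every cross-validation fold
(leakage-safe). `global_preproc=True` reproduces the variant where they
are fit once on the whole cohort.

## Nested cross-validation and tie rules

Per modality, classifier selection compares WeiRD and the SVM on the same
stratified inner folds by *pooled* balanced accuracy (per-class
accuracies computed over all held-out inner predictions at once). The
SVM's score is honest: inside each inner training split, C is chosen anew
by a second-level CV over the 16-value grid. If the SVM wins, C is then
re-estimated on the entire training fold; exact ties go to WeiRD (the
simpler, parameter-free model).

The weight search evaluates all 2^M vectors in {1,2}^M exhaustively
(refused above M = 16). A fresh stratified inner CV refits every
modality's preprocessing and classifier per inner fold — full nesting, so
the weight score carries no optimistic bias from reusing fitted models —
and all candidate vectors are scored on the cached inner decision values.
Ties break to the lowest total weight, then lexicographically. Training
subjects missing a modality are excluded from that modality's fits but
still scored through the omission rule, mirroring prediction time.

Remaining frozen conventions: the decision threshold is S > 0 for
patient, with the exact tie S = 0 (possible in binary fusion) going to
control; C-grid ties go to the smallest C (strongest regularization);
fold assignments are stratified and derived deterministically from the
run seed, so identical inputs and seed give byte-identical models.

Fusion mode — continuous decision values vs their signs (binary voting) —
is a prediction-time switch on a shared fitted state: the weight search
always scores with continuous fusion, and the ablation grid's binary
cells reuse the fitted folds of their continuous twins. This keeps the
3 × 2 × 2 grid (classifier fixed-SVM/fixed-WeiRD/optimized × weights
uniform/optimized × fusion continuous/binary) mutually consistent, at the
cost of not re-optimizing weights specifically for binary voting.

Decision values are fused on their native per-classifier scales by
default; `standardize_decisions=True` divides each modality's d by its
training-set standard deviation for scale-free fusion.

## Evaluation

- **Balanced accuracy** = (sensitivity + specificity)/2 with patient as
  the positive class; chance is 0.5 under any class imbalance, which is
  why the metric is used throughout, including as the inner-CV score.
- **Posterior inference**: sensitivity ~ Beta(TP+1, FN+1) and
  specificity ~ Beta(TN+1, FP+1) independently (uniform priors); the
  balanced-accuracy posterior is the distribution of their mean, computed
  by discrete convolution of the two Beta densities on a 4096-point grid
  — deterministic, no sampling. The p-value is P(balacc ≤ 0.5) and the
  interval the central 95% of the posterior. A seeded Monte-Carlo
  estimator exists as a cross-check and agrees to < 0.005 in the tests.
- **Cohen's kappa** between two modalities' LOO predictions uses the
  marginal-product chance correction, restricted to subjects where both
  modalities are available; two identical constant raters (p_e = 1) are
  defined as κ = 1. The kappa matrix picks, per modality, whichever
  classifier scored the better unimodal balanced accuracy (ties to
  WeiRD).
- **Leave-one-modality-out** re-runs the entire LOO evaluation once per
  excluded modality — selection and weights are re-optimized without the
  excluded modality, not merely zeroed out.

## Synthetic cohorts

No public dataset accompanies the problem domain, so the generator is a
first-class module. It emulates: several modalities of very different
dimensionality; class effects of varying strength; cross-modality
redundancy; per-modality missing subjects (MCAR, with guards keeping ≥ 1
modality per subject and ≥ 2 subjects per class per modality); and linear
covariate contamination (random per-feature loadings on age, gender,
site).

Construction, per subject i and modality m:

- a latent signal expression s = 1 + λ·l, where l mixes a common
  standard-normal subject factor with a modality factor at weight √ρ —
  ρ is exactly the cross-modality correlation of the latent signals.
  With certainty calibration on (λ > 0), subjects vary coherently in how
  strongly they express the class effect, so |d| genuinely predicts
  correctness — the regime in which continuous fusion should beat binary
  voting. λ defaults to 0.5–0.6 in the presets.
- informative features: x = noise + y·(d/2)·s, giving a between-class
  mean difference of d noise standard deviations; remaining features are
  pure noise. Noise is unit-variance Gaussian, matching the t-statistic
  assumptions of WeiRD's weighting; heavier tails are not modelled.
- the noise itself is drawn as √ρ·(shared pool) + √(1−ρ)·(own draw).
  Sharing the noise, not just the signal, is what makes ρ = 1 mean
  *redundant in the operative sense*: equal-shaped blocks become literal
  duplicates whose predictions coincide, which is the premise under which
  fusing them can yield no benefit. With signal-only sharing, independent
  feature noise still averages out across modalities and fusion keeps
  helping even at ρ = 1.

Presets fix the study scenarios: `null` (five modalities, d = 0
everywhere, 30+30 subjects), `complementary` (five blocks of 30/12/60/
100/30 features with per-feature effects 0.30–0.55, ρ = 0.2, certainty
calibration on, 60+60), `redundant` (five exchangeable 30-feature blocks,
ρ = 1), `single_informative` (one informative modality among four noise
ones, 30+30), and `lead_like` — a five-modality cohort with feature
counts 110/11/358/1461/110, 97 controls vs 119 patients, per-modality
availability (97/119, 97/119, 96/119, 74/80, 84/93), a dominant
structural modality (per-feature d = 0.50 on 16 features) over weaker
ones, ρ = 0.25 and mild covariate contamination. The per-feature effect
sizes were chosen once so that unimodal accuracies span the
strong-to-weak range typical of imaging cohorts (roughly 55–75%
balanced accuracy) and were not revisited.

What passing tests on these cohorts shows — and what it does not: the
generator produces Gaussian, feature-independent (up to the shared-pool
structure) data with exactly linear covariate effects and MCAR
missingness. Real imaging features are spatially autocorrelated,
heavier-tailed, and missing for systematic reasons; results on synthetic
cohorts validate the *machinery* (no leakage, correct fusion and
omission, calibrated nulls, benefit under complementarity), not expected
accuracy on any real population.

## Problem sizes and runtime choices

The default inner CV is stratified 10-fold with a 5-fold second level
(leave-one-out inner loops are available but quadratic in cost). The
simulation studies in the test suite and the acceptance script run with
3 inner folds and a 2-fold second level, and the acceptance script draws
the lead-like cohort at half scale (108 subjects); these are the
package's chosen demonstration sizes — one full nested LOO evaluation of
a 120-subject, five-modality cohort then takes ~25 s on one core.
Stratified fold counts adapt downward automatically when a class has
fewer members than folds.

## Known limitations

- Binary classification only; no probability calibration of decision
  values; no kernels besides RBF; no continuous (e.g. stacked-logistic)
  modality weighting beyond the {1,2} grid.
- The SVM importance map is a feature-space approximation; WeiRD's vote
  definition is one reasonable choice among several.
- The weight search optimizes continuous-fusion accuracy even when
  predictions are later binarized (see above).
- With very small training folds, indicator-coded covariates can produce
  levels unseen in a fold, which is an error by design; residualization
  should be disabled for tiny cohorts.
- κ between modalities is computed on pairwise-complete subjects; under
  informative missingness this estimand can differ from the full-cohort
  agreement.
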