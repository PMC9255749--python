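# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `gosepred`.

## Outcome model and encodings

The outcome is the 6-month Glasgow Outcome Scale–Extended with scores 2
and 3 merged: seven ordered categories (codes 1–7 for GOSE 1, 2/3, 4, 5,
6, 7, 8) and six thresholds (GOSE > 1, > 3, > 4, > 5, > 6, > 7). Two
output encodings are supported and are exact algebraic duals:

* **Multinomial**: seven nodes, softmax-constrained to sum to one;
  threshold exceedance probabilities are accumulated category
  probabilities and are non-increasing automatically.
* **Ordinal**: six nodes, one per threshold. The first pre-sigmoid value
  is `z_1`; each later one is `h_k = h_{k-1} − max(z_k, 0)`, so after the
  sigmoid the exceedance probabilities can never increase with the
  threshold. Monotonicity is structural — it holds for arbitrary
  (untrained) weights, which the tests assert.

`threshold_to_class_probs` differencing inverts the accumulation exactly;
conditional exceedance probabilities divide the higher threshold's
probability by the lower's.

## Model families

* **MNLR** — maximum-likelihood multinomial logistic regression
  (unpenalised; scikit-learn's LBFGS solver).
* **POLR** — cumulative-link logistic regression,
  `P(Y ≤ k) = σ(θ_k − xᵀβ)` (statsmodels ordered model), so positive β
  shifts patients towards better outcomes. POLR design matrices drop each
  one-hot group's reference level because the thresholds absorb the
  intercept.
* **DeepMN / DeepOR** — feedforward networks with the two heads above,
  trained with a class-weighted loss (inverse-frequency weights
  normalised to mean one), Adam, minibatches, and early stopping on a
  validation loss with best-weight restoration. Losses: weighted
  categorical negative log-likelihood (MN) and the sum over the six
  thresholds of weighted binary cross-entropies (OR) — the standard
  choices consistent with the two encodings. The network core is a small
  NumPy implementation (dense ReLU layers, He initialisation, inverted
  dropout, manual gradients); the architectures involved never exceed a
  few dense layers, so a full autodiff framework is unnecessary.
* **Token-embedding models (APM)** — each vocabulary entry has an
  embedding `v_i` and a significance parameter `s_i`; a patient with
  token set T is summarised as `u = (1/N) Σ_{i∈T} e^{s_i} v_i` with
  N = |T| (division by the token count, not the weight total). The
  summary feeds a trunk (possibly zero hidden layers) with an MN or OR
  head; embeddings, significance weights and head are trained jointly.
  Index 0 is an unrecognised-token placeholder with a zero-initialised
  embedding, so tokens first seen at test time are near-neutral. Whether
  missing-value NA tokens count in N: they do (they are tokens).

Defaults that matter: embedding dimension 64 (tests use 8–16), learning
rate 3e-3, patience 10 epochs, validation fraction 0.15. Exact
hyperparameter grids are exposed as configuration, not hard-coded.

## Resampling and imputation

The evaluation scaffold is 20 repeats of stratified 5-fold
cross-validation (100 partitions), stratified by the seven-category
outcome — the only meaningful stratification key here. Gradient-trained
models carve a stratified validation split (default 15% of the training
set) before any imputation is fitted, so nothing leaks into early
stopping. The validation fraction is configurable; published accounts of
this design are internally inconsistent about its size, so no single
value is canonical.

Missing concise predictors are completed by stochastic predictive mean
matching: chained equations, variables visited in order of increasing
missingness, 10 sweeps, approximate Bayesian coefficient draws, and each
missing cell filled with the observed value of one of 5 nearest training
donors by predicted mean (donors guarantee valid categorical levels). The
imputation model is fitted on training rows only; the outcome is included
as a covariate when completing the training table, and outcome-free
refitted models complete test tables. Unseen observed categorical levels
at completion time map to the training modal level with a warning. One
imputation per partition yields m = 100 completed datasets at full scale,
so resampling and imputation variability enter the bootstrap together.

## Tokenisation

Heterogeneous records become unique token sets: categorical values are
appended to the variable name (numerics zero-padded to width 2, e.g.
`GCSTotalScore_04`); continuous values are discretised into 20 quantile
bins learned from training data (`SystolicBloodPressure_BIN17`), with
duplicate quantile edges merged (ties reduce the effective bin count,
with a warning) and out-of-range test values clamped to the edge bins so
no new tokens appear at test time; free text is lower-cased and stripped
of spaces and special characters (`InjuryDescription_skullfracture`);
missing fields produce `Name_NA` tokens. The vocabulary is built from
training sequences only, with the placeholder at index 0.

## Metrics and inference

Patients are ranked by the expected number of thresholds exceeded (the
sum of the six exceedance probabilities). The ordinal c-index (ORC) is
the unweighted mean of pairwise Mann–Whitney AUCs over the 21 category
pairs, ties counting one half; it is invariant to any strictly increasing
transform of the ranking score (so the choice of score is innocuous) and
to category duplication (prevalence independence). The all-pairs
pairwise-AUC estimator is used; a Monte-Carlo test confirms it equals the
one-patient-per-category set-ranking interpretation. Somers' D_xy is
(C − D)/(C + D + T) over cross-outcome pairs and reduces to 2·AUC − 1
with two categories. Calibration uses the logistic recalibration slope
and a locally weighted calibration curve (span 0.75 on the probability
scale, robustness iterations disabled — they bias a binary-response
smoother towards the majority class — and clipped to [0, 1]); the ICI is
the mean absolute gap between the smoothed curve and the predictions.

Confidence intervals come from bootstrap bias-corrected cross-validation:
pooled out-of-fold predictions (one row per patient per partition per
configuration) are resampled at the level of unique patients — a
patient's rows always move together — 1,000 times by default; the mean
and percentile 95% interval are reported. Percentile rather than BCa
intervals are used: simpler, and only mean + 95% CI are reported.
Configuration dropping (BBCD-CV) bootstraps the partitions of a
configurations × partitions validation-metric matrix, records each
resample's winner (ties split evenly), and drops configurations whose
probability of being best falls below α = 0.01 — conservative, keeps
ties, and always leaves at least one survivor. The bootstrap resamples
pooled predictions, not model refits.

Descriptive-table p-values fit one proportional-odds regression on all
predictors concurrently per imputed dataset (Wald z for scalar
predictors, likelihood-ratio tests with k−1 degrees of freedom for
multi-categorical ones) and pool across imputations by the
z-transformation rule `z_pool = mean(z)/√(1 + var(z))`, which reduces to
the single-fit p-value when m = 1.

## Shapley attribution

Token attributions are Monte-Carlo permutation Shapley values (default
128 permutations per patient; exact enumeration whenever all orderings of
a small token set fit in the budget, and the two agree by construction).
"Token removed" means dropped from the set with N decremented; the empty
set aggregates to the zero vector, the model's no-information reference.
Aggregation: absolute values → mean over partitions per (patient, token)
→ mean over patients per token → predictor score = max over the
predictor's tokens; patients lacking a token contribute nothing to that
token's mean. Treatment/intervention and physician-impression predictors
are excluded from extended-set candidates — clinician impressions can
drive self-fulfilling prophecies (e.g. prognosis-driven withdrawal of
life-sustaining measures) — and the final extended schema is taken as
configuration rather than automated, because category-collapsing
decisions (e.g. one retirement indicator instead of ten employment
categories) are judgement calls on the token-level tables the pipeline
emits.

## Synthetic-data design

The generator reproduces the statistical structure the analysis assumes,
not any real patient data. Outcomes come either from the reference
marginal (20.5/16.9/7.7/14.6/12.9/13.3/14.0%) or from a
proportional-odds latent link whose cutpoints equal the logit cumulative
marginals, so a null linear predictor reproduces the marginal exactly (a
closed-form test target). The proportional-odds link was chosen as
ground truth so POLR recovery tests are well-posed. Concise predictor
marginals match the printed medians/IQRs and category frequencies: age is
truncated normal on [16, 95]; glucose and the protein biomarkers are
log-normal (right-skewed, as concentrations are); haemoglobin is normal.
Coefficient defaults are plausible per-SD effects with age, pupils and
Marshall CT class dominating — a design choice, since no generative
coefficients are published. Missingness is missing-completely-at-random
by default, calibrated to 54.77% complete cases and 14.71%
glucose+haemoglobin-only; the true mechanism is unknown, so an
outcome-dependent mode can be configured but is off by default.
Predictors are drawn independently: only marginal summaries are public,
so joint correlations are configurable, not calibrated — a real cohort's
predictor correlations would change absolute model performance, and
passing tests demonstrate correctness of the machinery, not clinical
performance levels.

Heterogeneous records target a median of ~532 non-missing unique tokens
per patient (IQR ≈ 486–580) from a pool of ~840 variables; a configurable
subset (24 by default) is informative — correlated with the latent linear
predictor — and the rest is noise. The free-text pool is a fixed list of
injury-description phrases, since only the normalisation rule matters
downstream. Tests use a proportionally scaled-down spec (~25–50 tokens
per patient).

## Problem sizes used in testing

To keep the suite fast the tests scale the study design down: smoke
experiments use 400 patients, 1–2 repeats and 50 bootstrap resamples;
coefficient-recovery runs use n = 5,000 over 20 seeds; bootstrap-coverage
checks use 100 runs of 120 patients × 2 partitions with B = 200;
large-sample metric checks use n = 10,000–40,000. The full-scale design
(n = 1,550, 100 partitions, B = 1,000, m = 100) runs through exactly the
same code paths via `ExperimentConfig`.

## Known limitations

* Deep architectures are intentionally small; no GPU path exists.
* The generator does not emulate cross-correlations among the ~1,100
  real-world variables, longitudinal outcome trajectories, or centre
  effects (no grouped cross-validation).
* Rubin's-rules pooling of model *coefficients* across imputations is out
  of scope; the analysis pools predictions.
* Non-convergence of a likelihood fit is flagged (`converged_`,
  warnings), not silently ignored, but no automatic restart is attempted.
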