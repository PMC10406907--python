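# Methods

`cwboost` implements component-wise gradient boosting of a generalized
linear model for a binary outcome, with ridge-penalized least-squares
base-learners whose penalties are calibrated to a common effective degrees
of freedom, plus three extensions: group base-learners, sparse-group
mixing, and a sequential ("K-step") variant that searches for interactions
only after main effects have been fitted.

## Model and fitting procedure

The outcome `y_i ∈ {0,1}` is modeled through a logit link,
`P(y_i = 1) = 1 / (1 + exp(-f_i))`, and the loss is the binomial negative
log-likelihood `l(y, f) = Σ_i log(1 + exp(f_i)) - y_i f_i`.  Fitting is
functional gradient descent:

1. Initialize `f` at the constant minimizing the loss — the log-odds of
   the training prevalence (a zero start is available via
   `offset_init="zero"`).
2. Compute the pseudo-residuals `u_i = y_i - 1/(1+exp(-f_i))`, the
   negative gradient of the loss at the current fit.
3. Fit every base-learner to `u` by ridge-penalized least squares and
   select the one whose fitted values have the smallest sum of squared
   errors to `u`.
4. Update `f ← f + η · ĥ` with learning rate `η ∈ (0,1)` (default 0.1) and
   repeat for `m_stop` iterations.

Each base-learner owns a block of design columns (one variable, one group
of variables, or one interaction term).  Because only one learner is
updated per iteration, an early-stopped run performs variable selection.

**Selection criterion.** The winner of step 3 minimizes the L2 distance of
its ridge fit to the pseudo-residuals, the model-based boosting
convention.  Writing the rule as "minimal loss applied to the data" is
ill-defined for a binomial loss evaluated on continuous pseudo-residuals,
so the L2 criterion is used and documented here prominently.  Ties —
which occur exactly, e.g. when two binary variables have identical
crosstabs with the outcome — go to the learner listed first; the
comparison uses a 1e-9 relative tolerance so the outcome does not depend
on floating-point summation order.

## Degrees-of-freedom calibration

For a block `X` with penalty `λ`, the hat matrix is
`S = X (XᵀX + λI)⁻¹ Xᵀ` and the effective degrees of freedom are
`df(λ) = tr(2S − SᵀS)`, computed spectrally as
`Σ_i [2 d_i/(d_i+λ) − (d_i/(d_i+λ))²]` over the eigenvalues `d_i` of
`XᵀX`.  Every learner's `λ` is calibrated so that `df(λ)` hits its target
(tolerance 1e-6): equal df across learners of different widths is what
makes the selection in step 3 fair, and penalizing complex blocks more
than simple ones biases the procedure toward simpler explanations.

`df(λ)` is strictly decreasing, so the inverse is found by bracketed root
search (`brentq` with bracket expansion); a single-column block has the
closed form `s = 1 − sqrt(1 − df)`, `λ = d(1−s)/s`, which serves as an
independent check of the root-finder in the test suite.  A target of zero
maps to `λ = +∞`: the learner is excluded and never selectable.  The
penalty applies to all block columns equally; the intercept lives entirely
in the offset and is never a selectable learner.

Penalties are calibrated once on the full training design and treated as
part of the base-learner definition; cross-validation folds recompute the
fold gram for the ridge solve but keep the calibrated `λ`.

## Design matrices

Variables are declared in a data dictionary (type, ordered categories,
group, moderator flag).  Binary and categorical variables are
reference-coded — first listed category as reference, `c` categories →
`c−1` indicator columns — which keeps the dominant binary variables as
one-column blocks with df 1.  All columns are centered on the training
rows and the constants stored, so test rows map into the identical column
space and the offset is interpretable as the marginal log-odds.
Interaction blocks are products of the parents' *uncentered* codes,
centered after the product; their width is the product of the parents'
widths.  Missing values are rejected rather than imputed, and constant
columns are rejected because their df calibration is undefined.

Every variable flagged as a moderator is paired with every other variable;
an unordered pair appears once.  Moderator–moderator pairs are included by
default (`include_moderator_pairs=False` disables them): with `q`
moderators among `p` variables this yields `q(p−q) + q(q−1)/2` terms, a
`p > n` design at survey scale.

## Model presets

* **mb** — one individual learner per variable, all df 1.  On a
  single-column block df 1 forces `λ = 0`; a categorical block gets the
  `λ > 0` solving `df(λ) = 1`.
* **mb int** — the mb learners plus one df-1 learner per interaction term,
  offered in parallel; the selection step decides between main and
  interaction effects.
* **sgb** — sparse group boosting with mixing parameter `α ∈ [0,1]`
  (default 0.5): per group `g` with `p_g` member variables, each member
  gets an individual learner with `df = α/p_g` and the group gets one
  learner over the union of its columns with `df = (1−α)/p_g`.  `α = 1`
  excludes all group learners (component-wise boosting); `α = 0` excludes
  all individual learners (group boosting).  `p_g` counts member
  variables, not expanded columns; variables outside any declared group
  form singleton groups.  A variant with unnormalized group df
  (`df_variant="unscaled-group"`) is available for comparison.
* **2-boost** — two-step boosting: stage 1 is the mb learner set, stage 2
  offers only interaction learners and continues from the stage-1 fitted
  function (equivalently, from its final pseudo-residual state).  Fitting
  main effects to convergence first removes the main-effect signal that
  interaction products would otherwise absorb, countering the selection
  bias toward interactions that a parallel search suffers when there are
  O(p²) interaction candidates.

## Early stopping

`m_stop` is chosen by stratified k-fold cross-validation (default 10
folds): each fold fits up to `cv_max` iterations (default 1000) and the
out-of-fold risk — mean binomial negative log-likelihood per observation,
the fitting loss — is recorded after every iteration; the chosen `m_stop`
minimizes the fold-mean curve, ties toward the smaller iteration count
(the sparser model).

For multi-stage fits the final model fits stage 1 once on the full
training data and stage 2 continues from it.  Inside stage 2's
cross-validation, however, each fold re-runs stage 1 on its own training
rows before measuring stage-2 out-of-fold risk.  Reusing the full-training
stage-1 fit inside CV leaks the held-out rows into the fold baseline and
biases the stage-2 stopping toward zero; with the leakage-free scheme the
second stage detects genuinely planted interactions while still stopping
at zero when interactions carry no out-of-fold signal.

## Interpretation

* **Variable importance** credits each iteration's reduction in the
  (unpenalized) negative log-likelihood to the selected learner and
  reports per-term totals and percentages of the overall reduction; the
  totals reconcile exactly with the ends of the risk path.  For two-stage
  fits the stages are concatenated, percentages taken relative to the
  combined reduction with a per-stage label retained.
* **Aggregated effects**: a term's coefficient is `η` times the sum of its
  per-step increments; `exp(coefficient)` is the odds ratio per design
  column against the reference category.
* **Partial effects** hold every other term's contribution at its training
  mean on the link scale (zero for centered columns, so an offset-only
  model yields a flat profile at the training prevalence) and sweep the
  chosen term's categories.  Means of contributions, not of raw
  covariates, keep the construction well-defined for categorical blocks.
* **Interaction profiles** fit a standalone logistic regression with both
  mains and their interaction, one interaction at a time and optionally
  per stratum, and report the fitted probability per joint category —
  identical to observed cell proportions when the model is saturated and
  all cells are populated.  Empty cells are flagged and left missing.

## Evaluation

Data are split 70/30 into training and test rows (train count rounded half
up; stratified by the outcome so small classes survive the split), with
models tuned and fitted on the training rows only.  Discrimination is the
rank-based AUC (Mann–Whitney statistic, ties counted one half), identical
to the trapezoidal area under the empirical ROC curve; a constant
predictor scores exactly 0.5.  AUC ignores calibration, which is a known
limitation, not a target of this package.

## Synthetic data

The generator emulates the structure the pipeline assumes: at full scale,
801 observations of 75 variables in 10 named groups (one four-region
geography, one three-level norms item, the rest binary with realistic
survey prevalences), 22 moderators — yielding 1397 variable-level
interaction pairs and an expanded interaction design wider than the sample
— and a Bernoulli outcome from a logistic model with planted effects.
Default plants are region main effects, an economic and two further
binary mains, and two region × goal interactions; magnitudes are fixed so
that component-wise boosting's test AUC lands in 0.70–0.85 at full scale
(measured mean 0.764 over ten seeds).  The intercept anchors the
prevalence near 358/801.  Scales below 1 shrink the observation count,
per-group variable counts and moderator count proportionally, and planted
effects are restricted to the variables present at that scale.

Covariates are drawn independently by default; a latent-Gaussian
within-group correlation knob exists to emulate group-level latent
variables.  Independence is the main gap between the generator and real
survey data: with independent parents, an interaction product carries a
sizable share of its parents' main-effect signal, so the penalty a
parallel interaction search pays for crowding out main effects is smaller
here than on correlated survey data.  Passing tests therefore demonstrate
the direction of the two-step advantage (lower selected-interaction share
and higher mean test AUC than the parallel search), not its real-data
magnitude.

## Problem sizes and protocols used in tests and the acceptance script

* Selection-oracle equivalence: 100 random fixtures (n ≤ 80, p ≤ 12,
  η = 0.1, 25 iterations) against a per-step full refit; 100% agreement
  required (50 fixtures in the acceptance script).
* Recovery of planted effects runs at full scale (n = 801) with fixed
  iteration budgets — 300 for mb, 400 + 300 for 2-boost — over 20 seeds.
  Fixed budgets rather than CV are used deliberately: CV stopping is
  conservative about interactions (that is its sparsity function), and the
  recovery property targets the selection mechanism, not the stopping
  rule.
* The two-step vs parallel comparison runs 20 replicates at generator
  scale 0.6 (n = 481, 525 interaction pairs, expanded design wider than
  n, 10-fold CV, cv_max 600), the package's chosen problem size for this
  study.

## Known limitations

* Binomial and (as a closed-form test hook) Gaussian losses only; no
  Poisson or survival families.
* No spline or other nonlinear base-learners; effects are linear on the
  link scale.
* No p-values or standard errors for boosted coefficients — importance
  and odds ratios are descriptive, not inferential.
* Missing data are rejected, not imputed; no survey weights.
* K-step presets are provided for K = 2 only, though the engine accepts
  any K.
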