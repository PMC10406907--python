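# cwboost

Interpretable component-wise ridge boosting for grouped, mostly binary
tabular data — the kind produced by structured surveys in environmental
epidemiology and agricultural economics, where a few hundred respondents
answer dozens of grouped questions and the analyst wants to know *which*
variables (and which variable pairs) are associated with a binary outcome,
not just how well a black box predicts it.

The package fits a logistic model by functional gradient descent.  Each
candidate term (a variable, a group of variables, or an interaction) is a
ridge-penalized least-squares base-learner, with its penalty λ calibrated
so that the effective degrees of freedom

    df(λ) = tr(2S − SᵀS),   S = X(XᵀX + λI)⁻¹Xᵀ,

are equal across learners — the calibration that makes component-wise
selection fair between simple and complex terms.  At every iteration all
learners are fit to the pseudo-residuals u = y − p̂ and only the best one
updates the fit, by a learning rate η; early stopping by stratified
cross-validation yields a sparse, directly interpretable model.

Four presets are provided:

| preset   | learners                                                        |
|----------|-----------------------------------------------------------------|
| `mb`     | one df-1 learner per variable (component-wise boosting)         |
| `mb-int` | main-effect and interaction learners offered in parallel        |
| `sgb`    | sparse group boosting: individual df α/p_g, group df (1−α)/p_g  |
| `2boost` | two-step: main effects first, then interactions only, continuing from the stage-1 fit |

`2boost` exists because a parallel search over the O(p²) interaction terms
of a p > n design is biased toward interactions regardless of true effect
sizes; fitting main effects to convergence first removes the signal that
interaction products would otherwise absorb.  Variable importance
(likelihood-reduction shares), odds ratios, partial effects and univariate
interaction profiles make the fitted models inspectable; a synthetic
survey generator with planted effects makes every stage testable.

## Worked example

Simulate a survey-like dataset (half scale: n = 400, 38 variables in 10
groups, 11 moderators) and fit component-wise boosting:

```python
from cwboost.synthetic import paper_like_spec, generate
from cwboost.cli import run_fit

data, dictionary, truth = generate(paper_like_spec(scale=0.5, seed=11))
res = run_fit(data, dictionary, "y", model="mb", seed=11, cv_max=600)
print(res["metrics"])
print(res["importance"].head(6))
```

```
model outcome      auc mstop  n_train  n_test  n_selected_terms
   mb       y 0.842197   600      280     120                11

          term       kind  step  reduction   percent
natural_assets individual     1  39.943703 77.148278
    economic_1 individual     1   4.697466  9.072804
       norms_1 individual     1   1.684869  3.254199
     spatial_1 individual     1   1.611520  3.112530
 biophysical_3 individual     1   1.515024  2.926156
       human_1 individual     1   0.980624  1.894002
```

The data were split 70/30 (stratified); the test AUC of 0.842 measures
discrimination on the held-out 120 rows.  The importance column says the
four-region geography variable (`natural_assets`) accounts for 77% of the
in-sample likelihood reduction, with the planted economic, spatial and
biophysical effects next — exactly the planted truth surfacing.  Running
all four presets on the same data:

```python
from cwboost.cli import run_compare
run_compare(data, dictionary, outcomes=["y"],
            models=["mb", "sgb", "mb-int", "2boost"], seed=11, cv_max=400)
```

```
 model outcome      auc  n_selected_interactions  one_minus_sparsity_pct
    mb       y 0.830484                      0.0                    0.00
   sgb       y 0.758310                      0.0                    0.00
mb-int       y 0.839506                     12.0                    3.41
2boost       y 0.844413                     16.0                    4.55
```

`one_minus_sparsity_pct` is the percentage of the 352 offered interaction
terms each model selected.

The same pipeline is available from the shell:

```bash
cwboost simulate --scale 0.5 --seed 11 --out-dir run/
cwboost fit --data run/data.csv --dictionary run/dictionary.csv \
        --outcome y --model 2boost --seed 11 --out-dir run/fit2boost/
cwboost interaction-profile --data run/data.csv --dictionary run/dictionary.csv \
        --outcome y --moderator natural_assets --partner goals_1 --out run/profile.csv
```

`fit` writes `metrics.csv`, `coefficients.csv` (with each learner's λ and
df), `importance.csv`, `roc.csv` and a `manifest.json` recording every
seed and stopping iteration, so a rerun with the same inputs is
byte-identical.

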