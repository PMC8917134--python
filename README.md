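# pairsig

Rank-based **gene-pair survival signatures**: construction, selection,
scoring and evaluation.

## The problem

Prognostic gene-expression signatures built from absolute expression values
travel poorly between cohorts: platform, library-prep and batch effects
rescale each sample's profile, so a risk formula fitted on one dataset is
miscalibrated on the next. A pairing strategy sidesteps this. For an ordered
gene pair (a, b) and sample s define the indicator

    lambda_ab(s) = 1  if  x_a(s) > x_b(s),  else 0   (ties score 0)

which depends only on the *within-sample ordering* of two genes and is
therefore invariant to any strictly increasing per-sample transformation of
the expression values. A signature over such indicators — a risk score

    risk(s) = sum_i  beta_i * lambda_i(s)

with Cox regression coefficients beta_i and a frozen dichotomisation cutoff
— can be applied to an external cohort without any renormalisation. This
package implements that methodology end to end for survival analysis of
tumour cohorts (the motivating application is immune-related lincRNA pairs
in liver cancer), together with a synthetic-cohort generator so every stage
can be exercised and validated without downloading patient data.

## Pipeline

1. **Pair features** (`build_pair_matrix`, `filter_low_variation`): all
   C(m, 2) indicators over a candidate gene list; pairs that are 0 or 1 in
   more than 80% of samples (strict inequality) are removed as
   non-informative.
2. **Selection** (`univariate_cox_screen`, `lasso_select`, `stepwise_cox`):
   per-pair univariate Cox proportional-hazards screen (Wald p < 0.05);
   L1-penalised Cox stabilised by repeating 10-fold cross-validated penalty
   selection (default 1000 times) under reshuffled folds and keeping pairs
   with nonzero coefficients in ≥ 50% of repeats; bidirectional stepwise
   multivariate Cox (AIC-ranked entry gated at p < 0.05, p-gated removal)
   yields the final pairs and betas.
3. **Scoring and cutoff** (`compute_risk_score`, `time_dependent_roc`,
   `optimal_cutoff`, `assign_groups`): risk scores are the plain linear
   predictor; the time-dependent ROC at a horizon t uses the
   cumulative/dynamic definition with marginal inverse-probability-of-
   censoring (IPCW) weights; the cutoff minimises the AIC of a
   dichotomised one-covariate Cox model (Youden index available as an
   alternative); samples with score > cutoff are high risk.
4. **Evaluation and associations** (`km_estimate`, `log_rank_test`,
   `cox_fit`, `validate_frozen_signature`, `spearman_assoc`,
   `group_compare`, `composition_test`, `tmb_from_maf`,
   `stratified_survival`): Kaplan–Meier and log-rank machinery, covariate-
   adjusted Cox independence testing, frozen-signature external validation,
   and the risk-group association toolkit including tumor mutational burden
   (non-synonymous mutations per megabase) from a MAF file.
5. **Synthetic cohorts** (`simulate_cohort`, `apply_batch_distortion`):
   log-normal expression with exchangeable gene correlation, planted causal
   pairs entering a Weibull proportional-hazards model, calibrated
   independent censoring, clinical covariates, and per-sample monotone
   batch distortions for robustness checks.

## Worked example

Discovery on a simulated 500-sample training cohort with three planted
causal pairs (log-hazards +1.5, +1.2, −1.0, 30% censoring), then frozen
validation on 300 held-out samples from the same generative truth:

```python
import pairsig as ps

cfg = ps.SimConfig(n_samples=800, n_genes=40, n_causal_pairs=3,
                   causal_betas=[1.5, 1.2, -1.0], censor_rate=0.3, seed=11)
full = ps.simulate_cohort(cfg)
train, val = full.split(500)

pm = ps.filter_low_variation(
    ps.build_pair_matrix(train.expression, list(train.expression.index)))
screened = ps.univariate_cox_screen(pm, train.survival)
sel = ps.lasso_select(pm.subset(list(screened.index)), train.survival,
                      n_repeats=50, seed=11)
model = ps.stepwise_cox(pm.subset(sel.selected), train.survival)

scores = ps.compute_risk_score(model, pm)
model.cutoff = ps.optimal_cutoff(scores, train.survival, horizon_t=1825.0)
report = ps.validate_frozen_signature(model, val.expression, val.survival,
                                      horizons=[365.0, 1095.0, 1825.0])
```

Output:

```
valid pairs after 80% constancy filter: 481
pairs passing univariate Cox screen (p < 0.05): 133
pairs kept by repeated CV-LASSO: 17
  LINC0012|LINC0033  beta = +1.784
  LINC0027|LINC0039  beta = -1.226
  LINC0004|LINC0024  beta = -1.097
  LINC0027|LINC0030  beta = -0.368
  LINC0015|LINC0026  beta = -0.345
  LINC0013|LINC0018  beta = +0.341
  LINC0004|LINC0019  beta = -0.290
  LINC0024|LINC0027  beta = +0.273
training 5-year AUC = 0.939, cutoff = 0.533
validation group sizes: {'low': 200, 'high': 100}
validation AUCs: 365d: 0.795, 1095d: 0.872, 1825d: 0.926
validation log-rank: chi2 = 69.4, p = 8.23e-17
planted pairs recovered: True
```

The three planted pairs head the signature with coefficients close to their
true log-hazards (signs flip when a pair is recovered in the reversed
orientation, since the reversed indicator is the complement of the
original); a handful of weaker correlated pairs follow. The frozen cutoff
separates the validation cohort into risk groups with clearly different
survival — the portability property the pair construction is designed for.

## Command line

Each stage is also exposed as a subcommand:

```bash
pairsig simulate --config cfg.json --out cohort/ --seed 3
pairsig pairs    --expr cohort/expression.tsv --out pairs.tsv
pairsig select   --pairs pairs.tsv --surv cohort/survival.tsv --seed 2 --out model.json
pairsig score    --model model.json --pairs pairs.tsv --out scores.tsv
pairsig evaluate --scores scores.tsv --surv cohort/survival.tsv --out report.json
pairsig validate --model model.json --expr expr.tsv --surv surv.tsv --out val.json
pairsig assoc    --scores scores.tsv --features features.tsv --out assoc.tsv
pairsig tmb      --maf cohort.maf --mb 38 --out tmb.tsv
```

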