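# Methods

This note documents the statistical procedures implemented in `pairsig`,
the modelling assumptions behind them, the tunable parameters that matter,
and the design decisions taken where the methodology is genuinely open.

## Pair indicators

For an ordered pair (a, b) and sample s the feature is
`lambda_ab(s) = 1 if x_a(s) > x_b(s) else 0`. Two conventions matter and are
fixed as follows:

- **Ties score 0.** Equal values (common in RNA-seq tables full of zeros)
  give the indicator 0, the natural reading of "1 if strictly greater".
  Because a monotone distortion maps equal values to equal values, tie
  handling does not break the invariance property.
- **Orientation.** Pairs are oriented (a, b) with a preceding b in the
  user-supplied gene list, and only one orientation is kept: the reversed
  indicator is the complement of the original (up to ties), i.e. perfectly
  collinear with it, so keeping both would make every downstream design
  matrix singular. Orientation only flips the sign of the fitted
  coefficient (the complementary shift is absorbed by the baseline hazard);
  any fixed convention is valid, and list order makes runs reproducible.

The **low-variation filter** removes pairs whose fraction of ones f is
strictly above `max_constancy` (default 0.80) or strictly below
`1 − max_constancy`; both boundaries are retained. The comparison is done
on integer one-counts with a 1e-9 guard so that f = 0.8 over, say, 100
samples is never misclassified by float representation.

## Selection chain

1. **Univariate Cox screen** (`alpha` = 0.05). One proportional-hazards
   model per pair, binary covariate, Efron tie handling. The Newton
   iteration is vectorised across all pairs (for a binary covariate every
   Efron risk-set sum reduces to a count of ones), converges to a score
   gradient below 1e-7 with at most 100 iterations, and caps |beta| at 15
   to contain monotone-likelihood (separated) covariates, which are flagged
   unconverged. Wald p-values, hazard ratios and 95% CIs are reported;
   constant pairs are skipped with a warning.
2. **Stability LASSO** (`n_repeats` = 1000, `keep_frac` = 0.5, `n_folds` =
   10). "Repeat the LASSO many times" is under-specified in general use;
   here each repeat reshuffles the cross-validation folds, selects the
   penalty minimising held-out partial-likelihood deviance over a 50-point
   path (largest-to-smallest, `alpha_min_ratio` = 0.01, the "lambda.min"
   convention), and records which pairs are nonzero in the full-data path
   at that penalty. Pairs selected in at least `keep_frac` of repeats are
   kept, together with their selection frequencies. Held-out deviance is
   the Breslow partial log-likelihood of the test fold at the train-fold
   coefficients, times −2.
3. **Stepwise multivariate Cox** (`p_enter` = 0.05). Bidirectional:
   a forward step adds the candidate minimising model AIC among those whose
   Wald p in the enlarged model is below `p_enter` (AIC ties broken by
   candidate order); backward steps remove included pairs whose p rises to
   `p_enter` or above; iterate to a fixed point with cycle detection.
   Duplicate and constant candidate columns are dropped up front, so
   perfectly collinear candidates cannot co-enter. An empty final model is
   a warned result, not an error. Multivariate fits use lifelines
   (Efron ties).

**Null behaviour.** The univariate screen is calibrated (pass rate ≈ alpha
on independent null pairs; verified to within 3 binomial standard errors in
the test suite). The chain as a whole, however, cannot drive a pure-noise
model to zero: pairs that survive the screen were selected on the full
cohort, so cross-validation folds drawn from the same cohort share the
spurious association and the LASSO stage retains most of them
(post-selection leakage). Final null models are therefore bounded by the
screen's false-discovery budget (≈ alpha × pairs tested) rather than
near-empty — an inherent property of running screen and penalised
regression on one dataset, which applies equally to the original
methodology. Stepwise pruning reduces the count further but not to zero.

## Risk score, time-dependent ROC and cutoff

The risk score is the unnormalised linear predictor `sum(beta_i *
lambda_i)`. Because it is a function of pair indicators only, scores are
bit-identical under any per-sample strictly monotone distortion of the
expression matrix — the package's central robustness property, asserted
end-to-end in the tests.

**IPCW cumulative/dynamic ROC** at horizon t: cases are samples with an
observed event by t, controls are samples still under observation after t.
Case contributions are weighted 1/G(T_i−), where G is the Kaplan–Meier
estimate of the censoring survival function (censoring treated as the
event) evaluated just before the case's event time — "marginal" weighting,
i.e. covariate-free. Sensitivity at threshold c is the weighted fraction of
cases with score > c; specificity is the unweighted fraction of controls
with score ≤ c (the controls' common weight 1/G(t) cancels). The AUC is the
trapezoidal integral taken in threshold order, which traces the ROC
staircase exactly and gives score ties half credit; with no censoring the
AUC equals the Mann–Whitney statistic to machine precision (property-tested
and cross-checked against scikit-survival's `cumulative_dynamic_auc` and a
brute-force weighted pairwise oracle).

**Optimal cutoff.** Candidates are midpoints of adjacent unique scores that
leave at least `min_group_frac` (default 0.1) of samples on each side — a
guard against degenerate splits. The default criterion fits a one-covariate
Cox model on each dichotomised indicator (reusing the vectorised batch
Newton) and returns the AIC-minimising cutoff; the Youden index
(sensitivity + specificity − 1 on the IPCW ROC at the stated horizon) is
available as `method="youden"`. Ties go to the smaller cutoff; both
criteria are shift-equivariant. Samples exactly at the cutoff are assigned
to the **low**-risk group (`score > cutoff` defines high). In finite
samples either criterion can place the cutoff one or two order statistics
away from a planted inter-cluster gap when a within-cluster sample's
survival crosses the evaluation horizon; tests therefore assert recovery of
the planted dichotomy (≥97% group agreement) rather than exact gap
containment.

**Frozen validation** recomputes indicators, scores and groups on an
external cohort with the stored pairs, betas and cutoff — no refitting —
and reports per-horizon AUCs, group sizes, between-group log-rank and KM
curves.

## Survival machinery and association tests

Kaplan–Meier estimation, log-rank tests (k groups, df = k−1) and
multivariate Cox fits delegate to lifelines; wrappers add the package's
validation (constant/collinear covariate rejection, separation warning at
|beta| > 10) and plain dataclass results. Grade and stage enter the
covariate-adjusted independence test as ordinal integers. Spearman
correlation (average ranks, t-approximation p), Wilcoxon rank-sum
(normal approximation with tie correction), Kruskal–Wallis and the Pearson
chi-square composition test (no continuity correction) delegate to scipy;
batch association runs emit raw p-values alongside Benjamini–Hochberg
adjusted ones, since downstream thresholds vary.

**TMB** is the count of MAF rows in the standard non-synonymous
classification set (Missense/Nonsense, Frame_Shift_Del/Ins, Splice_Site,
In_Frame_Del/Ins, Translation_Start_Site, Nonstop_Mutation) divided by the
sequenced territory; the denominator defaults to 38 Mb (a whole-exome
convention) and is configurable because published pipelines differ. A
median-split helper (ties → low) supports TMB-by-risk stratified survival:
four-cell KM, overall log-rank, and the two-group risk contrast within each
TMB stratum.

## Synthetic cohorts

The generator produces the structure the pipeline assumes, not realistic
RNA-seq counts:

- **Expression**: log-normal; gene i in sample j is
  `exp(mu_i + sigma * z_ij)` with gene means mu_i ~ N(0, `gene_mean_spread`)
  and z an exchangeable-correlation Gaussian (`gene_corr` shared across all
  gene pairs). This is rank-stable, produces a realistic mix of informative
  and near-constant pairs (roughly half of all pairs survive the 80% filter
  at the defaults), and is sufficient for every property the pipeline
  relies on. No negative-binomial counts, isoforms, tumour/normal pairing
  or immune-mixture structure are simulated.
- **Causal pairs**: disjoint random gene pairs whose indicator frequency
  falls in `causal_freq_band` (default 0.3–0.7), so planted effects are
  informative and survive the filter; indicators are computed exactly as
  the pair-features module defines them. Truth is stored as (gene_a,
  gene_b, beta) in the drawn orientation; recovery comparisons should treat
  pairs as unordered.
- **Event times**: inverse-transform sampling from Weibull proportional
  hazards, `S(t|x) = exp(−(t/scale)^shape · exp(eta))`, with eta the sum of
  planted pair effects plus optional clinical log-hazards (age per decade
  from 60, gender 0/1, grade/stage centred at 2.5; all zero by default so
  recovery is unconfounded).
- **Censoring**: exponential, with the rate solved numerically (bisection
  on the realised event times) so the expected censored fraction equals
  `censor_rate`; `censor_rate=0` disables censoring. Observed time is the
  minimum; all times are strictly positive by construction, and the readers
  drop any time ≤ 0 with a warning.
- **Defaults** mirror a liver-cancer discovery cohort: 374 samples,
  429 candidate genes, ~65% censoring for overall survival, Weibull shape
  1.2 and scale 1825 days, three planted pairs with log-hazards
  (1.5, 1.0, −1.0), gene correlation 0.2.
- **Batch distortion**: per-sample `scale · x^power + shift` with scale,
  power > 0 and shift ≥ 0 drawn log-/uniformly per sample — strictly
  increasing on non-negative values, hence rank- and tie-preserving within
  a sample.

Everything is a pure function of configuration plus seed. What passing
tests on these cohorts demonstrate is that the pipeline recovers planted
pair-level signal under proportional hazards with independent censoring;
they do not demonstrate robustness to confounded censoring, non-PH effects,
or signal carried by single genes rather than pairs.

## Problem sizes and numerical choices

- Tests and the acceptance script run the full pipeline at 500 training /
  300 validation samples, 40 genes (780 candidate pairs), 3 planted pairs
  with |beta| in [1.0, 1.5], 30% censoring, 50 LASSO repeats — sizes chosen
  so a complete run of the discovery chain takes seconds rather than hours
  while leaving all selection stages non-trivial. The library defaults
  (1000 repeats) match the published procedure.
- Newton tolerance 1e-7 on the score gradient, max 100 iterations, step
  clipping at ±2, |beta| cap 15 (batch univariate fits); lifelines defaults
  for multivariate fits.
- The dense pair matrix warns above 1e9 cells; at the motivating scale
  (35,604 pairs × 365 samples) it is ~13 M entries and unproblematic.
- AIC for the partial likelihood is `−2·loglik + 2·k`; ties in stepwise
  entry and in cutoff search are broken deterministically (candidate order,
  smaller cutoff).

## Known limitations

- The stability-selection reading of "run the LASSO 1000 times" (fold
  reshuffling + frequency threshold) is one defensible interpretation of an
  under-specified procedure; subsampling-based variants would give
  different selection frequencies.
- Time-dependent AUC has no confidence band; proportional-hazards
  diagnostics and competing risks are out of scope.
- The null behaviour of the full selection chain is bounded, not zero (see
  "Null behaviour" above); interpreting a small discovered signature on a
  single cohort still requires external validation, which is why the
  frozen-signature path exists.
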