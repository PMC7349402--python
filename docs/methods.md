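# Methods

This note documents the statistical model behind `morphage`, the defaults
and numerical choices, what the synthetic-data generator does and does not
emulate, and the framework's known limitations.

## The site-effect model

All harmonization in the package assumes the location/scale model

    y_ijv = α_v + W_ij β_v + γ_iv + δ_iv ε_ijv ,

for feature v of subject j at site i: a per-feature grand intercept α_v,
biological covariate effects β_v (here a single covariate, chronological
age, entering linearly), an additive site effect γ_iv, a strictly positive
multiplicative site effect δ_iv acting on the zero-mean noise ε. The three
strategies differ in what they do with γ and δ:

* **site-as-feature** does nothing to the data and instead appends the site
  label as one integer column (baseline site ↦ 0), leaving the regressor to
  model site however it can. It is the baseline against which the other
  strategies are judged.
* **OLS residualization** estimates site terms per feature by least squares
  with reference-site coding and subtracts them. It ignores δ and shares
  ComBat's covariate dilemma.
* **ComBat** standardizes each feature by its fitted mean structure and
  pooled scale, estimates per-site location (γ̂) and scale (δ̂²) effects on
  the standardized data, shrinks them across features with parametric
  empirical Bayes — Gaussian prior for locations, inverse-gamma for squared
  scales, hyperparameters by method of moments — and removes the shrunk
  effects.

### Numerical choices in the ComBat fit

* Identifiability: the site-indicator design uses all S columns plus the
  covariates; the grand intercept is the site-size-weighted mean of the
  per-site coefficients, equivalent to a size-weighted zero-sum constraint
  on site effects.
* Pooled scale: the per-feature pooled variance is the residual sum of
  squares of the full design divided by `N − rank(design)` (the classic
  pooled/unbiased estimator). This convention makes the no-shrinkage
  (`eb=False`) adjustment exactly idempotent — re-harmonizing already
  harmonized data reproduces it to machine precision — which the
  `RSS/N` convention misses at O(1/n).
* EB iterations: the conditional updates for (γ*, δ²*) run until the
  maximum absolute change falls below 1e-4, at most 100 iterations. Sites
  whose δ̂² spread across features degenerates (zero variance, e.g. a
  single-site fit) fall back to the direct estimates rather than divide by
  zero.
* Approximate idempotence of the EB path: shrinkage deliberately leaves a
  γ̂ − γ* remainder, so a second EB pass is not a no-op; it is an order of
  magnitude smaller than the first (tested), and exactly zero in direct
  mode.
* Errors are raised early and name the offender: sites with fewer than two
  subjects, zero-variance features, rank-deficient designs (covariates
  collinear with site indicators), unknown site labels at apply time.

### Covariates and confounding

When site membership predicts age (sites recruiting narrow age windows),
removing site effects without protecting age removes the between-site part
of the age signal — the central failure mode the framework demonstrates.
Supplying age as covariate protects the *modeled* (linear-in-age)
association; trajectories that are strongly nonlinear in age leave an
unmodeled component in the residual whose between-site structure is
partially absorbed into the site effects. The preservation guarantee is
therefore evaluated on linear-trajectory features, as the mean change in
|age–feature correlation| across informative features: at desk scale
(N = 300) each individual correlation change carries irreducible noise of
the order of the within-site slope standard error, which no harmonization
method can beat, while the mean over features is a calibrated summary.

## Regressors and rankings

* **Linear ε-SVR** (`SVR(kernel="linear")`, ε = 0.1, C = 1): SVM-RFE
  refits the model on the surviving features and removes the 10% (at least
  one) with the smallest squared weight per iteration; the reversed
  elimination order is the ranking. One-at-a-time elimination is available
  (`rfe_step_fraction=0`). The libsvm stopping tolerance is exposed
  (`svr_tol`, default 1e-3); reduced-scale experiments use 1e-2, which
  leaves the weight vector essentially unchanged (correlation 0.9999 on
  representative data) at half the cost.
* **Random forest** (500 trees by default, mtry = P/3, minimum node size
  5): out-of-bag MSE averages, per observation, the predictions of trees
  for which it was out of bag. Permutation importance permutes a feature's
  OOB values per tree and averages the OOB-MSE increase over trees; an
  injectable permutation hook exists for testing (the identity permutation
  yields exactly zero importance). Reduced-scale experiments use 100
  trees; tree count at that scale is a sizing choice, importance rankings
  stabilize well below 500 trees for P ≤ 200.
* **Lasso**: features are standardized to unit variance inside the fit
  (penalty fairness); λ is chosen on a log-spaced grid by an inner k-fold
  CV (default 5) minimizing MAE, ties toward the sparser model; λ = 0
  falls back to ordinary least squares. Coefficients are reported on the
  original scale; ranking uses the standardized-scale |coefficient|, with
  zeros last in feature order.

## Stepwise repeated cross-validation

Folds are stratified by age quartile so every fold spans the age range;
`n_repeats × n_folds` (default 10 × 10) rounds each rank features on the
training folds only, then refit on the top-k for every k in the grid
(default: steps of 5 to 100, then steps of 50 up to P). `k_opt` minimizes
the mean held-out MAE, ties toward the smaller k. Per-subject final
predictions average the held-out predictions across repeats at `k_opt`.
Harmonization is fitted once on the full dataset before CV, matching the
workflow the framework evaluates; the resulting (mild) information leakage
is a property of that workflow, and fitting within folds can be composed
manually from `combat_fit`/`combat_apply` for sensitivity analysis.

## Consensus and stability

RRA scores each feature by ρ = min_j BetaCDF(r_(j); j, L−j+1) over the
sorted normalized ranks r observed in the L lists, with p = min(ρ·L, 1).
Features absent from a truncated (top-k) list contribute no order statistic
— the uniform-null treatment of partial rankings — rather than an imputed
rank, avoiding optimistic bias. Note that the ρ score is not monotone under
list addition: a new list can contribute a dominating order statistic, so
adding rankings can sharpen a feature's p-value; p-values are invariant to
list relabeling. The lasso path uses the selection-frequency criterion
(default threshold 0.8, chosen well above the 0.5 chance level). Consensus
sets are truncated to `k_opt` features so that set sizes are comparable
across strategies.

Stability between two strategies is the Jaccard index of their consensus
*region* sets (features mapped to regions; the synthetic global region is
excluded), with a one-sided permutation test: the null redraws
size-preserving random subsets of the full region vocabulary (default
10 000 draws, add-one-corrected p). The exact null expectation is available
in closed form through the hypergeometric overlap distribution and is used
as a test oracle.

## Age models and the AUC deviation index

Predicted age is regressed on chronological age with polynomials of degree
1–3; adjusted R² (1 − (1−R²)(n−1)/(n−d−1)) selects the best, ties toward
the lower degree. The normalized area under the fitted curve integrates
ŷ(y) − age_min over the observed age range and scales by 2/(range)²; the
shift by age_min makes the index exactly 1 for the ideal model ŷ = y on
any range, above 1 for overestimation, below 1 for underestimation; the
signed deviation AUC − 1 is reported. The polynomial integral is evaluated
in closed form and agrees with adaptive quadrature to 1e-9 (tested).

## The synthetic-data generator

The generator draws cohorts directly from the site-effect model: γ_iv ~
N(0, site_location_sd²); δ_iv log-normal with unit mean and shape
`site_scale_shape` (guaranteeing δ > 0); ε Gaussian. A configurable subset
of features is age-informative with linear or concave-quadratic
trajectories (standardized over the cohort so β is an effect size in
noise-SD units); quadratic peaks fall in the upper half of the age range,
mirroring developmental curves that flatten in adulthood. Defaults emulate
the multi-site autism-cohort setting the framework targets: 654 male
subjects (374 controls, 280 ASD) over 17 sites, ages 6.47–39.39 with a
young-skewed Beta(1.5, 3.5) distribution per site window, 1213 features in
the standard four-category layout, 100 informative features. Site–age
confounding is induced by staggered per-site age windows
(`confounded_age_ranges`).

What the generator does *not* emulate: spatial correlation among features
(real morphometric features are strongly inter-correlated within regions),
group differences between NC and ASD feature distributions, heavy-tailed
measurement error, missingness, or scanner drift within site. Passing
tests therefore demonstrate the statistical machinery under the assumed
location/scale model, not robustness to violations of it.

Reduced problem sizes used by the test-suite experiments (N = 300, P = 200,
2 × 5 CV; planted-signal runs at P = 100) are the package's own sizing
choices for desk-scale verification; conclusions at those scales are
qualitative (orderings, calibrations, recovery), not effect-size estimates
for any real cohort.

## Known limitations

* Only parametric EB ComBat; no non-parametric variant, reference-batch
  mode, or longitudinal extension.
* The covariate model is linear in age; strongly nonlinear biological
  trajectories are only partially protected under confounding.
* No correction of the systematic age underestimation (brain-age-delta
  bias); the AUC index quantifies it but does not remove it.
* The MAD outlier utility operates on any scalar vector and uses the raw
  (unscaled) MAD with default k = 3; the 1.4826 Gaussian-consistency
  constant is deliberately not applied, and both are configurable.
* Stability is pairwise; no generalized overlap statistic for three or
  more strategies.
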