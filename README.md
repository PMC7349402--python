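# morphage

Multi-site harmonization and brain-age prediction for morphometric
feature tables.

Brain morphometry aggregated across acquisition sites carries scanner- and
protocol-driven "batch effects" that confound downstream analysis. When the
biological variable of interest (chronological age) is itself entangled
with site — sites recruiting restricted age ranges — naive site removal can
erase the very signal an age-prediction model needs. `morphage` implements
a complete evaluation framework for this problem, aimed at researchers
analysing multi-site structural-MRI feature tables (e.g. FreeSurfer
extractions): it harmonizes, predicts age, selects stable anatomical
features, and quantifies how much the selected features depend on the
harmonization choice.

## What it implements

**Harmonization.** Three strategies over a subjects × features matrix
`y_ijv` (site *i*, subject *j*, feature *v*):

- *site-as-feature* — leave the data untouched and append the site label
  as one extra integer-coded feature;
- *OLS residualization* — fit `y_ijv = α_v + W_ij β_v + Z_ij θ_v + ε_ijv`
  per feature and subtract the site terms `Z θ̂_v`;
- *ComBat* — model `y_ijv = α_v + W_ij β_v + γ_iv + δ_iv ε_ijv` with
  additive (γ) and multiplicative (δ) site effects, shrink their per-site
  estimates across features with parametric empirical Bayes (Gaussian prior
  on locations, inverse-gamma on squared scales), and remove them — with or
  without age in the covariate matrix `W`.

**Age prediction with embedded ranking.** Linear ε-insensitive SVR ranked
by recursive feature elimination on squared weights; random-forest
regression ranked by out-of-bag permutation importance
(`OOB-MSE = 1/n Σ (y_i − ȳ̂_i^OOB)²` per tree, permuted-minus-actual,
averaged over trees); lasso with the penalty chosen by an inner CV, the
nonzero support being the per-round selection.

**Stepwise repeated CV.** For each of `n_repeats × n_folds` rounds, rank on
the training folds only, refit on the top-k features for every k in a grid,
and score MAE and R² on the held-out fold; `k_opt` minimizes the mean MAE.

**Consensus and stability.** Per-round rankings are aggregated with robust
rank aggregation (beta order statistics of normalized ranks, Bonferroni
corrected) or an 80% selection-frequency criterion; consensus sets from two
harmonization strategies are compared with the Jaccard index
`J(A,B) = |A∩B| / |A∪B|` against a size-preserving permutation null.

**Age-model deviation.** Predicted-vs-chronological age is fit with
polynomials of degree 1–3, the best chosen by adjusted R², and summarized
by the normalized area under the fitted curve,
`AUC = 2/(age_max−age_min)² ∫ (ŷ(y) − age_min) dy`, which is exactly 1 for
the ideal model, below 1 under systematic age underestimation.

A synthetic-data module generates multi-site cohorts from the same
location/scale model (known ground-truth site effects, configurable
site–age confounding, 1213-feature default schema: 21 global + 544
cortical + 240 sub-cortical + 408 white-matter features), so every stage is
testable against recoverable truth.

## Worked example

```python
import numpy as np
from morphage import (SyntheticConfig, RegressorSpec, CVPlan,
                      confounded_age_ranges, simulate_dataset, harmonize,
                      run_stepwise_cv, select_k_opt, collect_predictions,
                      fit_age_models, select_best_fit, auc_deviation_index,
                      site_effect_statistic)
from morphage.schema import FeatureSchema

records = [dict(feature_id=f"f{i}", category="cortical", region=f"r{i % 10}",
                metric="volume", hemisphere="none") for i in range(100)]
schema = FeatureSchema.from_records(records)

config = SyntheticConfig(
    n_sites=6, subjects_per_site=[40] * 6,
    age_range_per_site=confounded_age_ranges(6, overlap=2.0),
    n_informative_features=15, trajectory="linear",
    site_location_sd=0.2, site_scale_shape=0.15, seed=0)
dataset, truth = simulate_dataset(config, schema)

noise = ~truth.informative
f_pre = site_effect_statistic(dataset)
harmonized = harmonize(dataset, "combat_age_covariate")
f_post = site_effect_statistic(harmonized)
print(f"mean site F on noise features: {f_pre[noise].mean():.2f} -> {f_post[noise].mean():.2f}")
print(f"mean site F on age-informative features: {f_pre[~noise].mean():.2f} -> {f_post[~noise].mean():.2f}")

spec = RegressorSpec(family="l1_linear",
                     lambda_grid=tuple(np.logspace(-3, 1, 8)), seed=0)
result = run_stepwise_cv(harmonized, spec, [5, 10, 20, 50, 100],
                         CVPlan(n_repeats=2, n_folds=5, seed=0))
summary = select_k_opt(result)
print(f"k_opt={summary.k_opt}  MAE={summary.mae_mean:.2f}+/-{summary.mae_sd:.2f}  "
      f"R2={summary.r2_mean:.2f}")

preds = collect_predictions(result, summary.k_opt)
ages = harmonized.subjects.loc[preds.index, "age"].to_numpy()
best = select_best_fit(fit_age_models(ages, preds.to_numpy()))
auc = auc_deviation_index(best)
print(f"best age-model degree={best.degree}  adjusted R2={best.adjusted_r2:.2f}  "
      f"AUC deviation={auc.deviation:+.2f}")
```

Output:

```
mean site F on noise features: 2.68 -> 0.55
mean site F on age-informative features: 18.20 -> 17.05
k_opt=100  MAE=2.00+/-0.10  R2=0.88
best age-model degree=2  adjusted R2=0.88  AUC deviation=-0.04
```

Reading: on a site–age confounded cohort, ComBat with the age covariate
drives the site F statistic of pure-noise features toward its null (2.68 →
0.55) while the age-informative features keep their age-driven between-site
differences (18.2 → 17.1) — site variation removed, biological variation
preserved. The lasso stepwise CV then predicts age with a mean absolute
error of 2.0 years (k_opt = 100 because the lasso performs its own
selection inside the fit, so extra candidates do not hurt). The best
predicted-vs-chronological fit is a concave quadratic whose AUC deviation
of −0.04 indicates a slight systematic age underestimation.

The same experiment end-to-end (all strategies × regressors × groups,
consensus sets, category/ROI frequencies, stability JSON, manifest) runs
from the command line:

```sh
morphage all --seed 0 --out results/run1            # full 1213-feature layout
morphage all --seed 0 --n-features 200 --out results/quick  # reduced scale
morphage simulate --n-sites 17 --n-subjects 654 --out data/synthetic
```

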