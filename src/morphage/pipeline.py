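"""Orchestration of the full strategies x regressors x groups experiment.

For every group x harmonization strategy x regressor the pipeline runs the
stepwise CV, picks k_opt, aggregates per-round rankings into a consensus
feature set, summarizes it by category and region, and fits the age models
on the averaged out-of-fold predictions. The best regressor (lowest mean
MAE at k_opt averaged over the retained strategies) is then used for the
pairwise Jaccard stability comparison of region sets across strategies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .age_models import auc_deviation_index, fit_age_models, select_best_fit
from .consensus import (ConsensusSet, category_frequency, frequency_select,
                        roi_frequency, rra_aggregate)
from .data import MorphometryDataset, write_dataset
from .harmonize import STRATEGIES, harmonize
from .regressors import FAMILIES, RegressorSpec
from .simulate import SyntheticConfig, simulate_dataset
from .stability import jaccard_permutation_test
from .stepwise import (CVPlan, collect_predictions, derive_seed, run_stepwise_cv,
                       select_k_opt)


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    schema: object | None = None  # FeatureSchema; None -> full default layout
    strategies: tuple[str, ...] = STRATEGIES
    regressors: tuple[str, ...] = FAMILIES
    regressor_overrides: dict = field(default_factory=dict)
    cv: CVPlan = field(default_factory=CVPlan)
    k_grid: list[int] | None = None
    groups: tuple[str, ...] = ("NC", "ASD")
    consensus_threshold: float = 0.8
    consensus_alpha: float = 0.05
    stability_n_perm: int = 10_000
    seed: int = 0
    outdir: str | Path | None = None

    def spec_for(self, family: str, seed: int) -> RegressorSpec:
        kwargs = dict(self.regressor_overrides.get(family, {}))
        kwargs.update(family=family, seed=seed)
        return RegressorSpec(**kwargs)


def build_consensus(result, spec_family: str, k_opt: int,
                    threshold: float, alpha: float) -> ConsensusSet:
    """Aggregate per-round rankings/selections into the consensus set.

    RRA on the per-round top-k_opt partial lists for SVR and the forest;
    the frequency criterion on the support matrix for the lasso. Either
    way the set is truncated to at most k_opt features.
    """
    if spec_family == "l1_linear":
        return frequency_select(result.selection_matrix(), threshold,
                                result.feature_ids, truncate_to=k_opt)
    lists = result.rank_lists(top_k=k_opt)
    return rra_aggregate(lists, result.feature_ids, alpha=alpha,
                         truncate_to=k_opt)


def run_experiment(config: RunConfig) -> dict:
    """Run the full experiment; returns (and optionally writes) the report
    bundle. Fully deterministic given the configuration."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    dataset, truth = simulate_dataset(config.synthetic, config.schema)
    if outdir:
        write_dataset(dataset, outdir / "dataset.csv")
        dataset.schema.to_json(outdir / "schema.json")
        truth.to_json(outdir / "simulation_truth.json")

    perf_rows = []
    age_rows = []
    cat_rows = []
    consensus_sets: dict[tuple, ConsensusSet] = {}
    region_sets: dict[tuple, set] = {}
    results: dict[tuple, object] = {}

    for group in config.groups:
        try:
            group_ds = dataset.select_group(group)
        except ValueError:
            continue
        for strategy in config.strategies:
            harmonized = harmonize(group_ds, strategy)
            k_grid = config.k_grid or None
            for family in config.regressors:
                seed = derive_seed(config.seed, hash_key(group, strategy, family))
                spec = config.spec_for(family, seed)
                plan = CVPlan(config.cv.n_repeats, config.cv.n_folds,
                              derive_seed(config.seed, hash_key(group, strategy)))
                grid = ([k for k in k_grid if k <= harmonized.n_features]
                        if k_grid else None)
                result = run_stepwise_cv(harmonized, spec, grid, plan)
                summary = select_k_opt(result)
                results[(group, strategy, family)] = result
                perf_rows.append(dict(group=group, strategy=strategy,
                                      regressor=family, k_opt=summary.k_opt,
                                      mae_mean=summary.mae_mean,
                                      mae_sd=summary.mae_sd,
                                      r2_mean=summary.r2_mean,
                                      r2_sd=summary.r2_sd))
                consensus = build_consensus(result, family, summary.k_opt,
                                            config.consensus_threshold,
                                            config.consensus_alpha)
                consensus_sets[(group, strategy, family)] = consensus
                rois = roi_frequency(consensus, harmonized.schema)
                region_sets[(group, strategy, family)] = (
                    set(rois.index) - {"global"})
                cat = category_frequency(consensus, harmonized.schema)
                cat_rows.append(dict(group=group, strategy=strategy,
                                     regressor=family,
                                     **{f"freq_{c}": float(v)
                                        for c, v in cat.items()}))
                preds = collect_predictions(result, summary.k_opt)
                ages = harmonized.subjects.loc[preds.index, "age"].to_numpy()
                fits = fit_age_models(ages, preds.to_numpy())
                best = select_best_fit(fits)
                auc = auc_deviation_index(best)
                age_rows.append(dict(
                    group=group, strategy=strategy, regressor=family,
                    degree=best.degree,
                    coefficients=";".join(f"{c:.6g}" for c in best.coefficients),
                    adjusted_r2=best.adjusted_r2, auc_index=auc.auc,
                    auc_deviation=auc.deviation))
                if outdir:
                    tag = f"{group}_{strategy}_{family}"
                    result.performance.to_csv(
                        outdir / f"performance_{tag}.csv", index=False)
                    pd.DataFrame(result.rankings).to_csv(
                        outdir / f"rankings_{tag}.csv", index=False)
                    result.predictions.to_csv(
                        outdir / f"predictions_{tag}.csv", index=False)
                    consensus.table.to_csv(outdir / f"consensus_{tag}.csv")

    performance = pd.DataFrame(perf_rows)
    age_models = pd.DataFrame(age_rows)
    categories = pd.DataFrame(cat_rows)

    # best regressor: lowest mean MAE at k_opt averaged over strategies
    stability = {}
    if not performance.empty and len(config.strategies) >= 2:
        by_family = performance.groupby("regressor")["mae_mean"].mean()
        best_family = str(by_family.idxmin())
        universe = [r for r in dataset.schema.regions if r != "global"]
        strategies = list(config.strategies)
        for group in config.groups:
            for i, s_a in enumerate(strategies):
                for s_b in strategies[i + 1:]:
                    key_a = (group, s_a, best_family)
                    key_b = (group, s_b, best_family)
                    if key_a not in region_sets or key_b not in region_sets:
                        continue
                    rois_a = region_sets[key_a]
                    rois_b = region_sets[key_b]
                    if not rois_a and not rois_b:
                        continue
                    res = jaccard_permutation_test(
                        rois_a, rois_b, universe,
                        n_perm=config.stability_n_perm,
                        seed=derive_seed(config.seed,
                                         hash_key(group, s_a, s_b)))
                    stability[f"{group}|{s_a}|{s_b}"] = dict(
                        regressor=best_family, **res.to_dict())

    bundle = dict(performance=performance, age_models=age_models,
                  categories=categories, consensus=consensus_sets,
                  stability=stability, results=results, dataset=dataset)
    if outdir:
        performance.to_csv(outdir / "performance_summary.csv", index=False)
        age_models.to_csv(outdir / "age_models.csv", index=False)
        categories.to_csv(outdir / "category_frequency.csv", index=False)
        (outdir / "stability.json").write_text(json.dumps(stability, indent=1))
        manifest = dict(
            seed=config.seed,
            strategies=list(config.strategies),
            regressors=list(config.regressors),
            groups=list(config.groups),
            cv=dict(n_repeats=config.cv.n_repeats, n_folds=config.cv.n_folds,
                    seed=config.cv.seed),
            k_grid=config.k_grid,
            consensus=dict(threshold=config.consensus_threshold,
                           alpha=config.consensus_alpha),
            stability_n_perm=config.stability_n_perm,
            synthetic=dict(n_sites=config.synthetic.n_sites,
                           subjects_per_site=config.synthetic.subjects_per_site,
                           n_informative=config.synthetic.n_informative_features,
                           noise_sd=config.synthetic.noise_sd,
                           site_location_sd=config.synthetic.site_location_sd,
                           site_scale_shape=config.synthetic.site_scale_shape,
                           seed=config.synthetic.seed),
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle


def hash_key(*parts: str) -> int:
    """Stable small integer from string parts (no Python hash randomness)."""
    acc = 0
    for part in parts:
        for ch in str(part):
            acc = (acc * 131 + ord(ch)) % 1_000_000_007
    return acc
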