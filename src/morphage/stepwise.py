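"""Repeated-CV stepwise framework: rank on training folds, evaluate nested
top-k models, pick the k minimizing mean held-out MAE.

Each of n_repeats x n_folds rounds ranks the features using only the
training folds (SVM-RFE, OOB permutation importance or inner-CV lasso,
depending on the regressor family), then refits the regressor on the top-k
features for every k in the grid and scores MAE / R^2 on the held-out fold.
Folds are stratified by age quartile so every fold spans the age range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import MorphometryDataset
from .metrics import mae, r2
from .regressors import (
    FeatureRanking,
    RegressorSpec,
    fit_lasso_inner_cv,
    fit_predict_linear_svr,
    fit_random_forest,
    rf_permutation_importance,
)


def derive_seed(*keys: int) -> int:
    """Deterministic child seed below 2^31 from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


@dataclass
class CVPlan:
    n_repeats: int = 10
    n_folds: int = 10
    seed: int = 0

    @property
    def n_rounds(self) -> int:
        return self.n_repeats * self.n_folds


def default_k_grid(p: int) -> list[int]:
    """Top-k grid: steps of 5 up to 100, then steps of 50 up to P."""
    grid = [k for k in range(5, 101, 5) if k <= p]
    grid += [k for k in range(150, p + 1, 50)]
    if p not in grid:
        grid.append(p)
    return sorted(set(grid))


@dataclass
class StepwiseCVResult:
    """Per-round rankings, per-k fold performance, and fold predictions."""

    k_grid: list[int]
    feature_ids: list[str]
    rankings: np.ndarray                 # (rounds, P) feature indices, best first
    selections: np.ndarray | None        # (rounds, P) 0/1 lasso support
    performance: pd.DataFrame            # round, repeat, fold, k, mae, r2
    predictions: pd.DataFrame            # round, repeat, fold, k, subject_id, y_true, y_pred
    fold_test_indices: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_rounds(self) -> int:
        return self.rankings.shape[0]

    def rank_lists(self, top_k: int | None = None) -> list[list[str]]:
        """Per-round ranked feature-id lists (optionally truncated)."""
        out = []
        for row in self.rankings:
            ids = [self.feature_ids[j] for j in row]
            out.append(ids[:top_k] if top_k else ids)
        return out

    def selection_matrix(self) -> np.ndarray:
        if self.selections is None:
            raise ValueError("selections only recorded for l1_linear")
        return self.selections


@dataclass
class KOptSummary:
    k_opt: int
    mae_mean: float
    mae_sd: float
    r2_mean: float
    r2_sd: float


def _age_strata(y: np.ndarray, n_bins: int = 4) -> np.ndarray:
    return pd.qcut(y, n_bins, labels=False, duplicates="drop")


def _rank_features(x: np.ndarray, y: np.ndarray, spec: RegressorSpec,
                   seed: int) -> tuple[FeatureRanking, np.ndarray | None]:
    from .regressors import rank_svm_rfe  # local to keep import graph flat

    round_spec = RegressorSpec(**{**spec.__dict__, "seed": seed})
    if spec.family == "linear_svr":
        return rank_svm_rfe(x, y, round_spec), None
    if spec.family == "random_forest":
        model, _ = fit_random_forest(x, y, round_spec)
        return rf_permutation_importance(model, seed=seed), None
    if spec.family == "l1_linear":
        _, support, ranking = fit_lasso_inner_cv(x, y, round_spec)
        return ranking, support.astype(np.int8)
    raise ValueError(spec.family)


def _fit_predict(x_tr: np.ndarray, y_tr: np.ndarray, x_te: np.ndarray,
                 spec: RegressorSpec, seed: int) -> np.ndarray:
    round_spec = RegressorSpec(**{**spec.__dict__, "seed": seed})
    if spec.family == "linear_svr":
        return fit_predict_linear_svr(x_tr, y_tr, x_te, round_spec)
    if spec.family == "random_forest":
        model, _ = fit_random_forest(x_tr, y_tr, round_spec)
        return model.predict(x_te)
    if spec.family == "l1_linear":
        fit, _, _ = fit_lasso_inner_cv(x_tr, y_tr, round_spec)
        return fit.predict(x_te)
    raise ValueError(spec.family)


def run_stepwise_cv(dataset: MorphometryDataset, spec: RegressorSpec,
                    k_grid: list[int] | None = None,
                    plan: CVPlan | None = None) -> StepwiseCVResult:
    """Run the full repeated-CV stepwise analysis for one regressor.

    Deterministic given ``plan.seed`` and ``spec.seed``; no information
    from a round's test fold reaches ranking or fitting in that round.
    """
    plan = plan or CVPlan()
    x = dataset.matrix()
    y = dataset.ages
    n, p = x.shape
    k_grid = sorted(k_grid) if k_grid else default_k_grid(p)
    if k_grid[0] < 1 or k_grid[-1] > p:
        raise ValueError(f"k_grid must lie within [1, {p}]")
    subject_ids = np.asarray(dataset.subjects.index)
    strata = _age_strata(y)

    rankings = np.zeros((plan.n_rounds, p), dtype=int)
    selections = (np.zeros((plan.n_rounds, p), dtype=np.int8)
                  if spec.family == "l1_linear" else None)
    perf_rows = []
    pred_rows = []
    fold_test_indices = []
    round_idx = 0
    for rep in range(plan.n_repeats):
        skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                              random_state=derive_seed(plan.seed, rep))
        for fold, (tr, te) in enumerate(skf.split(x, strata)):
            seed_r = derive_seed(plan.seed, spec.seed, rep, fold)
            ranking, support = _rank_features(x[tr], y[tr], spec, seed_r)
            rankings[round_idx] = ranking.order
            if support is not None:
                selections[round_idx] = support
            fold_test_indices.append(te)
            for k in k_grid:
                cols = ranking.top(k)
                yhat = _fit_predict(x[np.ix_(tr, cols)], y[tr],
                                    x[np.ix_(te, cols)], spec, seed_r)
                perf_rows.append((round_idx, rep, fold, k,
                                  mae(y[te], yhat), r2(y[te], yhat)))
                for sid, yt, yp in zip(subject_ids[te], y[te], yhat):
                    pred_rows.append((round_idx, rep, fold, k, sid,
                                      float(yt), float(yp)))
            round_idx += 1

    performance = pd.DataFrame(
        perf_rows, columns=["round", "repeat", "fold", "k", "mae", "r2"])
    predictions = pd.DataFrame(
        pred_rows,
        columns=["round", "repeat", "fold", "k", "subject_id", "y_true", "y_pred"])
    return StepwiseCVResult(k_grid, list(dataset.values.columns), rankings,
                            selections, performance, predictions,
                            fold_test_indices)


def select_k_opt(result: StepwiseCVResult) -> KOptSummary:
    """The k minimizing mean MAE over rounds; ties go to the smaller k."""
    if result.performance.empty:
        raise ValueError("empty stepwise result")
    by_k = result.performance.groupby("k")
    means = by_k["mae"].mean()
    k_opt = int(means.index[np.argmin(means.to_numpy())])
    at = result.performance[result.performance["k"] == k_opt]
    return KOptSummary(
        k_opt=k_opt,
        mae_mean=float(at["mae"].mean()),
        mae_sd=float(at["mae"].std(ddof=1)),
        r2_mean=float(at["r2"].mean()),
        r2_sd=float(at["r2"].std(ddof=1)),
    )


def collect_predictions(result: StepwiseCVResult, k: int) -> pd.Series:
    """Per-subject mean of the held-out predictions at ``k``.

    Every subject is held out once per repeat, so each mean averages
    n_repeats predictions.
    """
    at = result.predictions[result.predictions["k"] == k]
    if at.empty:
        raise ValueError(f"no predictions recorded at k={k}")
    return at.groupby("subject_id")["y_pred"].mean()
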