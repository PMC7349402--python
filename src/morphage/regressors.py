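"""Age regressors with embedded feature-importance procedures.

Three regressor families are supported, each paired with its own ranking
method:

* linear epsilon-insensitive SVR, ranked by recursive feature elimination
  on squared weights (SVM-RFE);
* random forest regression, ranked by out-of-bag permutation importance
  (per tree, the increase in OOB MSE after permuting a feature's OOB
  values, averaged over trees);
* lasso with the penalty chosen by an inner cross-validation minimizing
  MAE; the nonzero support is the per-round selection and features rank by
  absolute standardized coefficient.

Model fitting delegates to scikit-learn; the elimination loop, the OOB
bookkeeping and the inner-CV selection are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
from sklearn.svm import SVR

FAMILIES = ("linear_svr", "random_forest", "l1_linear")


@dataclass
class RegressorSpec:
    """Settings for one regressor family.

    Defaults follow common practice for this analysis: epsilon-SVR margin
    0.1 with unit regularization, forests of 500 trees with P/3 candidate
    predictors per split and minimum node size 5, and a log-spaced lasso
    penalty grid searched by 5-fold inner CV.
    """

    family: str
    epsilon: float = 0.1
    C: float = 1.0
    mtry: int | None = None          # None -> round(P / 3)
    ntree: int = 500
    min_node_size: int = 5
    lambda_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.logspace(-3, 1, 10)))
    rfe_step_fraction: float = 0.1   # 0 -> one-at-a-time elimination
    n_inner_folds: int = 5
    svr_tol: float = 1e-3            # libsvm stopping tolerance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.family == "l1_linear" and not self.lambda_grid:
            raise ValueError("lambda_grid must be nonempty for l1_linear")


@dataclass
class FeatureRanking:
    """A permutation of candidate features, best first.

    ``order`` holds column indices; ``scores`` is aligned with ``order``
    (importance of the feature at each rank position).
    """

    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, int)
        self.scores = np.asarray(self.scores, float)
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("ranking must be a permutation (no repeats)")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def _check_training(x: np.ndarray, y: np.ndarray) -> None:
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in training data")
    if len(y) < 2:
        raise ValueError("need at least 2 training subjects")


def _svr(spec: RegressorSpec) -> SVR:
    return SVR(kernel="linear", epsilon=spec.epsilon, C=spec.C,
               tol=spec.svr_tol, cache_size=500)


def fit_predict_linear_svr(train_x, train_y, test_x, spec: RegressorSpec) -> np.ndarray:
    """Fit linear epsilon-SVR on the training fold; predict the test fold."""
    train_x = np.asarray(train_x, float)
    train_y = np.asarray(train_y, float)
    _check_training(train_x, train_y)
    if np.ptp(train_y) == 0:
        raise ValueError("constant training target")
    model = _svr(spec)
    model.fit(train_x, train_y)
    return model.predict(np.asarray(test_x, float))


def rank_svm_rfe(train_x, train_y, spec: RegressorSpec) -> FeatureRanking:
    """SVM-RFE: iteratively drop the lowest-|weight|^2 block of features.

    Each iteration fits the linear SVR on the surviving features, scores
    them by squared weight, and removes the lowest-scoring
    ``rfe_step_fraction`` (at least one). The reversed elimination order is
    the ranking.
    """
    x = np.asarray(train_x, float)
    y = np.asarray(train_y, float)
    _check_training(x, y)
    if np.ptp(y) == 0:
        raise ValueError("constant training target")
    remaining = list(range(x.shape[1]))
    eliminated: list[int] = []
    elim_scores: list[float] = []
    while remaining:
        if len(remaining) == 1:
            eliminated.append(remaining[0])
            elim_scores.append(np.inf)
            break
        model = _svr(spec)
        model.fit(x[:, remaining], y)
        w = np.ravel(np.asarray(model.coef_))
        scores = w ** 2
        n_drop = max(1, int(len(remaining) * spec.rfe_step_fraction))
        n_drop = min(n_drop, len(remaining) - 1)
        drop_pos = np.argsort(scores, kind="stable")[:n_drop]
        for pos in sorted(drop_pos, key=lambda p: (scores[p], remaining[p])):
            eliminated.append(remaining[pos])
            elim_scores.append(float(scores[pos]))
        remaining = [f for i, f in enumerate(remaining) if i not in set(drop_pos)]
    order = np.array(eliminated[::-1], int)
    return FeatureRanking(order, np.array(elim_scores[::-1]))


@dataclass
class RandomForestModel:
    """A fitted forest plus the per-tree bootstrap bookkeeping."""

    forest: RandomForestRegressor = field(repr=False)
    train_x: np.ndarray = field(repr=False)
    train_y: np.ndarray = field(repr=False)
    oob_masks: list[np.ndarray] = field(repr=False)  # per tree, bool (n,)

    def predict(self, x) -> np.ndarray:
        return self.forest.predict(np.asarray(x, float))

    def oob_mse(self) -> float:
        """MSE of the averaged predictions from trees where each
        observation was out of bag (observations with >=1 OOB tree)."""
        n = len(self.train_y)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, mask in zip(self.forest.estimators_, self.oob_masks):
            if mask.any():
                total[mask] += tree.predict(self.train_x[mask])
                count[mask] += 1
        has = count > 0
        if not has.any():
            raise ValueError("no out-of-bag observations")
        pred = total[has] / count[has]
        return float(np.mean((self.train_y[has] - pred) ** 2))


def fit_random_forest(train_x, train_y, spec: RegressorSpec) -> tuple[RandomForestModel, float]:
    """Fit a bootstrap forest and report its out-of-bag MSE."""
    x = np.asarray(train_x, float)
    y = np.asarray(train_y, float)
    _check_training(x, y)
    n, p = x.shape
    if n < 5:
        raise ValueError("random forest needs at least 5 observations")
    mtry = spec.mtry if spec.mtry is not None else max(1, round(p / 3))
    forest = RandomForestRegressor(
        n_estimators=spec.ntree,
        max_features=min(mtry, p),
        min_samples_leaf=spec.min_node_size,
        bootstrap=True,
        random_state=spec.seed % (2 ** 31),
        n_jobs=1,
    )
    forest.fit(x, y)
    oob_masks = []
    for sample_idx in forest.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[sample_idx] = False
        oob_masks.append(mask)
    model = RandomForestModel(forest, x, y, oob_masks)
    return model, model.oob_mse()


def rf_permutation_importance(model: RandomForestModel, seed: int = 0,
                              permutation_fn=None) -> FeatureRanking:
    """Out-of-bag permutation importance, averaged over trees.

    For each tree and feature, the feature's values on that tree's OOB rows
    are permuted and the resulting OOB MSE increase over the unpermuted OOB
    MSE is recorded; the mean over trees ranks the features (descending).
    ``permutation_fn(rng, n) -> index array`` is a hook for tests (an
    identity permutation yields exactly zero importance).
    """
    rng = np.random.default_rng(seed)
    permute = permutation_fn or (lambda r, n: r.permutation(n))
    x, y = model.train_x, model.train_y
    p = x.shape[1]
    importance = np.zeros(p)
    used = 0
    for tree, mask in zip(model.forest.estimators_, model.oob_masks):
        if not mask.any():
            continue
        used += 1
        x_oob = x[mask]
        y_oob = y[mask]
        base_mse = np.mean((y_oob - tree.predict(x_oob)) ** 2)
        n_oob = x_oob.shape[0]
        work = x_oob.copy()
        for f in range(p):
            perm = permute(rng, n_oob)
            saved = work[:, f].copy()
            work[:, f] = saved[perm]
            perm_mse = np.mean((y_oob - tree.predict(work)) ** 2)
            work[:, f] = saved
            importance[f] += perm_mse - base_mse
    if used == 0:
        raise ValueError("no tree has out-of-bag observations")
    importance /= used
    order = np.lexsort((np.arange(p), -importance))
    return FeatureRanking(order, importance[order])


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    return (x - mean) / scale_safe, mean, scale_safe


def _lasso_coefs(x: np.ndarray, y: np.ndarray, alpha: float,
                 seed: int) -> tuple[np.ndarray, float]:
    """Lasso coefficients and intercept; alpha=0 falls back to OLS."""
    if alpha == 0:
        design = np.hstack([np.ones((x.shape[0], 1)), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return coef[1:], float(coef[0])
    model = Lasso(alpha=alpha, max_iter=20000, tol=1e-5,
                  random_state=seed % (2 ** 31))
    model.fit(x, y)
    return model.coef_.copy(), float(model.intercept_)


@dataclass
class LassoFit:
    """Lasso fitted at the inner-CV-selected penalty, on standardized
    features, with coefficients reported on the original scale."""

    alpha: float
    coef: np.ndarray            # original-scale coefficients
    coef_std: np.ndarray        # standardized-scale coefficients
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    cv_mae: dict[float, float]  # mean inner-CV MAE per grid value

    def predict(self, x) -> np.ndarray:
        xs = (np.asarray(x, float) - self.feature_mean) / self.feature_scale
        return xs @ self.coef_std + self.intercept


def fit_lasso_inner_cv(train_x, train_y, spec: RegressorSpec,
                       n_inner_folds: int | None = None
                       ) -> tuple[LassoFit, np.ndarray, FeatureRanking]:
    """Choose the lasso penalty by inner k-fold CV (minimum MAE), fit at
    the chosen penalty, and return (fit, support mask, ranking).

    Ties in CV MAE resolve toward the larger (sparser) penalty. Features
    are standardized to unit variance inside the fit; zeros rank last in
    feature order.
    """
    x = np.asarray(train_x, float)
    y = np.asarray(train_y, float)
    _check_training(x, y)
    grid = sorted(spec.lambda_grid)
    if not grid:
        raise ValueError("empty lambda grid")
    k = n_inner_folds or spec.n_inner_folds
    xs, mean, scale = _standardize(x)
    cv_mae: dict[float, float] = {}
    if len(grid) > 1:
        kf = KFold(n_splits=min(k, len(y)), shuffle=True,
                   random_state=spec.seed % (2 ** 31))
        for alpha in grid:
            errs = []
            for tr, te in kf.split(xs):
                coef, icept = _lasso_coefs(xs[tr], y[tr], alpha, spec.seed)
                errs.append(np.mean(np.abs(y[te] - (xs[te] @ coef + icept))))
            cv_mae[alpha] = float(np.mean(errs))
        best = min(grid, key=lambda a: (cv_mae[a], -a))
    else:
        best = grid[0]
        cv_mae[best] = np.nan
    coef_std, intercept = _lasso_coefs(xs, y, best, spec.seed)
    coef = coef_std / scale
    fit = LassoFit(best, coef, coef_std, intercept, mean, scale, cv_mae)
    support = coef_std != 0
    p = len(coef_std)
    # descending |standardized coefficient|; zeros last, ties by index
    key = np.where(support, np.abs(coef_std), -1.0)
    order = np.lexsort((np.arange(p), -key))
    return fit, support, FeatureRanking(order, key[order])


def expected_oob_fraction(n: int, n_draws: int, seed: int = 0) -> float:
    """Monte-Carlo estimate of the bootstrap out-of-bag fraction.

    Draws ``n_draws`` bootstrap samples of size n with replacement and
    returns the mean fraction of indices never sampled (approaches
    1/e ~ 36.8% for large n).
    """
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_draws)
    for i in range(n_draws):
        sample = rng.integers(0, n, size=n)
        fractions[i] = 1.0 - np.unique(sample).size / n
    return float(fractions.mean())
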