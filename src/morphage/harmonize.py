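"""Multi-site harmonization: site-as-feature, OLS residualization, ComBat.

Three strategies for dealing with site (scanner/protocol) effects are
provided, mirroring the comparison this package implements:

* ``no_harmonization`` — leave the data untouched and append the site label
  as one extra integer-coded feature, letting the regressor model site in a
  data-driven way;
* OLS residualization — per feature, regress on site indicators (optionally
  with biological covariates) and subtract the fitted site terms;
* ComBat — model per-feature additive (location) and multiplicative (scale)
  site effects, shrink their estimates across features with parametric
  empirical Bayes (Gaussian prior on locations, inverse-gamma on squared
  scales), and remove them. Supplying the biological covariate of interest
  (age) protects its association with the features when site and covariate
  are confounded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MorphometryDataset
from .schema import FeatureSchema

STRATEGIES = ("no_harmonization", "combat_age_covariate", "combat_no_covariate")

SITE_FEATURE_ID = "site_code"


def _covariate_matrix(dataset: MorphometryDataset, covariates) -> tuple[np.ndarray | None, list[str] | None]:
    """Resolve covariates into an (N, c) matrix.

    ``covariates`` may be None, a list of subject-metadata column names, or
    an explicit matrix. Returns (matrix, names); names is None for explicit
    matrices.
    """
    if covariates is None:
        return None, None
    if isinstance(covariates, (list, tuple)) and all(isinstance(c, str) for c in covariates):
        names = list(covariates)
        if not names:
            return None, None
        missing = [c for c in names if c not in dataset.subjects.columns]
        if missing:
            raise ValueError(f"unknown covariate columns: {missing}")
        return dataset.subjects[names].to_numpy(float), names
    w = np.atleast_2d(np.asarray(covariates, float))
    if w.shape[0] != dataset.n_subjects:
        w = w.T
    if w.shape[0] != dataset.n_subjects:
        raise ValueError("covariate matrix row count must equal n_subjects")
    return w, None


def append_site_feature(dataset: MorphometryDataset) -> MorphometryDataset:
    """Append one integer-coded site column (baseline site maps to 0).

    Sites are sorted; the smallest label is the baseline and site s is
    encoded as its zero-based offset from it. The new feature is labelled
    category "global".
    """
    sites = dataset.sites
    order = {s: i for i, s in enumerate(sorted(set(sites)))}
    code = np.array([order[s] for s in sites], dtype=float)
    values = dataset.values.copy()
    values[SITE_FEATURE_ID] = code
    table = dataset.schema.table.copy()
    extra = pd.DataFrame(
        [dict(category="global", region="global", metric="site-code",
              hemisphere="none")],
        index=pd.Index([SITE_FEATURE_ID], name=table.index.name),
    )
    schema = FeatureSchema(pd.concat([table, extra]))
    return MorphometryDataset(dataset.subjects.copy(), values, schema)


def _site_design(sites: np.ndarray) -> tuple[np.ndarray, list[int], np.ndarray]:
    labels = sorted(set(sites.tolist()))
    z = np.zeros((len(sites), len(labels)))
    for i, lab in enumerate(labels):
        z[sites == lab, i] = 1.0
    return z, labels, z.sum(axis=0)


def residualize_site_ols(dataset: MorphometryDataset, covariates=None) -> MorphometryDataset:
    """Remove OLS-estimated site effects, keeping covariate contributions.

    Per feature, fits y = alpha + W beta + Z theta + eps with reference-site
    coding (the smallest site label is the baseline whose mean defines
    alpha) and returns y - Z theta_hat.
    """
    w, _ = _covariate_matrix(dataset, covariates)
    sites = dataset.sites
    z_full, labels, counts = _site_design(sites)
    if len(labels) < 2:
        raise ValueError("residualization requires at least 2 sites")
    z = z_full[:, 1:]  # reference coding: baseline site dropped
    n = dataset.n_subjects
    blocks = [np.ones((n, 1))]
    if w is not None:
        blocks.append(w)
    blocks.append(z)
    design = np.hstack(blocks)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        tiny = [lab for lab, c in zip(labels, counts) if c < 2]
        detail = f"; sites with <2 subjects: {tiny}" if tiny else ""
        raise ValueError(
            "rank-deficient harmonization design (site indicators collinear "
            f"with covariates){detail}")
    coef, *_ = np.linalg.lstsq(design, dataset.matrix(), rcond=None)
    theta = coef[-z.shape[1]:]
    return dataset.with_values(dataset.matrix() - z @ theta)


@dataclass
class SiteEffectEstimates:
    """Fitted ComBat parameters.

    ``gamma_star`` / ``delta_star`` are the (EB-shrunk) per-site location
    and scale effects on the standardized scale, one row per site in
    ``site_labels`` order. ``theta`` holds the reference-coded OLS site
    coefficients when the OLS model is fitted separately.
    """

    site_labels: list[int]
    alpha: np.ndarray                 # (P,) grand intercepts
    beta: np.ndarray | None           # (c, P) covariate coefficients
    gamma_star: np.ndarray            # (S, P)
    delta_star: np.ndarray            # (S, P), strictly positive
    pooled_sd: np.ndarray             # (P,)
    eb_hyperparams: dict = field(default_factory=dict)
    covariate_names: list[str] | None = None
    feature_ids: list[str] | None = None
    theta: np.ndarray | None = None
    eb: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_labels": self.site_labels,
            "alpha": self.alpha.tolist(),
            "beta": None if self.beta is None else self.beta.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "eb_hyperparams": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                               for k, v in self.eb_hyperparams.items()},
            "covariate_names": self.covariate_names,
            "feature_ids": self.feature_ids,
            "eb": self.eb,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SiteEffectEstimates":
        d = json.loads(Path(path).read_text())
        return cls(
            site_labels=d["site_labels"],
            alpha=np.array(d["alpha"]),
            beta=None if d["beta"] is None else np.array(d["beta"]),
            gamma_star=np.array(d["gamma_star"]),
            delta_star=np.array(d["delta_star"]),
            pooled_sd=np.array(d["pooled_sd"]),
            eb_hyperparams={k: np.array(v) if isinstance(v, list) else v
                            for k, v in d["eb_hyperparams"].items()},
            covariate_names=d["covariate_names"],
            feature_ids=d["feature_ids"],
            eb=d["eb"],
        )


def _eb_site_update(s_site: np.ndarray, g_hat: np.ndarray, d_hat_sq: np.ndarray,
                    g_bar: float, tau_sq: float, a_prior: float, b_prior: float,
                    tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional EB updates for one site's location/scale effects."""
    n = s_site.shape[0]
    g = g_hat.copy()
    d_sq = d_hat_sq.copy()
    for _ in range(max_iter):
        g_new = (n * tau_sq * g_hat + d_sq * g_bar) / (n * tau_sq + d_sq)
        ss = ((s_site - g_new) ** 2).sum(axis=0)
        d_new = (b_prior + 0.5 * ss) / (n / 2 + a_prior - 1)
        change = max(np.max(np.abs(g_new - g)), np.max(np.abs(d_new - d_sq)))
        g, d_sq = g_new, d_new
        if change < tol:
            break
    return g, d_sq


def combat_fit(dataset: MorphometryDataset, covariates=None, *, eb: bool = True,
               tol: float = 1e-4, max_iter: int = 100) -> SiteEffectEstimates:
    """Fit the ComBat location/scale model.

    Steps: (1) per-feature OLS of grand mean, covariate effects and
    provisional site effects under the size-weighted zero-sum constraint;
    (2) standardization of residual data by the pooled per-feature scale;
    (3) parametric EB shrinkage of per-site location effects toward a
    Gaussian prior and squared scale effects toward an inverse-gamma prior,
    hyperparameters estimated across features by method of moments and
    solved by iterative conditional updates (``eb=False`` skips shrinkage
    and keeps the direct per-site estimates).
    """
    w, names = _covariate_matrix(dataset, covariates)
    y = dataset.matrix()
    n, p = y.shape
    sites = dataset.sites
    z, labels, counts = _site_design(sites)
    small = [lab for lab, c in zip(labels, counts) if c < 2]
    if small:
        raise ValueError(f"every site needs >=2 subjects; offending: {small}")
    zero_var = np.where(y.std(axis=0) == 0)[0]
    if zero_var.size:
        fid = dataset.values.columns[zero_var[0]]
        raise ValueError(f"zero-variance feature: {fid!r}")

    design = z if w is None else np.hstack([z, w])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient ComBat design "
                         "(covariates collinear with site indicators)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    s_count = z.shape[1]
    gamma_prov = coef[:s_count]                      # (S, P) per-site means
    beta = coef[s_count:] if w is not None else None
    alpha = (counts / n) @ gamma_prov                # size-weighted grand mean

    resid = y - design @ coef
    dof = n - np.linalg.matrix_rank(design)
    pooled_var = (resid ** 2).sum(axis=0) / dof
    if (pooled_var <= 0).any():
        fid = dataset.values.columns[int(np.argmax(pooled_var <= 0))]
        raise ValueError(f"zero residual variance for feature {fid!r}")
    pooled_sd = np.sqrt(pooled_var)

    stand_mean = alpha[None, :] + (w @ beta if w is not None else 0.0)
    s_data = (y - stand_mean) / pooled_sd

    gamma_hat = np.empty((s_count, p))
    delta_hat_sq = np.empty((s_count, p))
    for i, lab in enumerate(labels):
        rows = s_data[sites == lab]
        gamma_hat[i] = rows.mean(axis=0)
        delta_hat_sq[i] = rows.var(axis=0, ddof=1)

    hyper: dict = {}
    if eb:
        if p < 2:
            raise ValueError("parametric EB needs >=2 features to estimate "
                             "priors; use eb=False for single features")
        gamma_star = np.empty_like(gamma_hat)
        delta_star_sq = np.empty_like(delta_hat_sq)
        g_bar = gamma_hat.mean(axis=1)
        tau_sq = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat_sq.mean(axis=1)
        s2 = delta_hat_sq.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_prior = (2 * s2 + m ** 2) / s2
            b_prior = (m * s2 + m ** 3) / s2
        hyper = dict(gamma_bar=g_bar, tau_sq=tau_sq, a_prior=a_prior,
                     b_prior=b_prior)
        for i, lab in enumerate(labels):
            if not np.isfinite(a_prior[i]) or s2[i] <= 0:
                # degenerate scale spread across features: no shrinkage
                gamma_star[i], delta_star_sq[i] = gamma_hat[i], delta_hat_sq[i]
                continue
            gamma_star[i], delta_star_sq[i] = _eb_site_update(
                s_data[sites == lab], gamma_hat[i], delta_hat_sq[i],
                g_bar[i], tau_sq[i], a_prior[i], b_prior[i], tol, max_iter)
    else:
        gamma_star, delta_star_sq = gamma_hat, delta_hat_sq

    return SiteEffectEstimates(
        site_labels=[int(lab) for lab in labels],
        alpha=alpha,
        beta=beta,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta_star_sq),
        pooled_sd=pooled_sd,
        eb_hyperparams=hyper,
        covariate_names=names,
        feature_ids=list(dataset.values.columns),
        eb=eb,
    )


def combat_apply(dataset: MorphometryDataset,
                 estimates: SiteEffectEstimates) -> MorphometryDataset:
    """Remove the fitted site effects from a dataset.

    Standardizes with the fitted grand mean / covariate terms and pooled
    scale, subtracts the per-site location effect, divides by the per-site
    scale effect, and restores the original scale and centring.
    """
    if estimates.feature_ids is not None and \
            list(dataset.values.columns) != estimates.feature_ids:
        raise ValueError("dataset features do not match fitted estimates")
    unknown = set(dataset.sites.tolist()) - set(estimates.site_labels)
    if unknown:
        raise ValueError(f"unknown site labels: {sorted(unknown)}")
    if estimates.covariate_names is not None:
        w = dataset.subjects[estimates.covariate_names].to_numpy(float)
    elif estimates.beta is not None:
        raise ValueError("estimates were fitted with an explicit covariate "
                         "matrix; refit with named covariates to re-apply")
    else:
        w = None
    y = dataset.matrix()
    stand_mean = estimates.alpha[None, :] + (
        w @ estimates.beta if w is not None else 0.0)
    s_data = (y - stand_mean) / estimates.pooled_sd
    out = np.empty_like(s_data)
    pos = {lab: i for i, lab in enumerate(estimates.site_labels)}
    sites = dataset.sites
    for lab in set(sites.tolist()):
        i = pos[lab]
        rows = sites == lab
        out[rows] = (s_data[rows] - estimates.gamma_star[i]) / estimates.delta_star[i]
    return dataset.with_values(out * estimates.pooled_sd + stand_mean)


def site_effect_statistic(dataset: MorphometryDataset) -> np.ndarray:
    """Per-feature one-way ANOVA F statistic of site.

    Constant features yield NaN with a warning rather than an error.
    """
    y = dataset.matrix()
    sites = dataset.sites
    labels = sorted(set(sites.tolist()))
    if len(labels) < 2:
        raise ValueError("site F statistic requires >=2 sites")
    n = y.shape[0]
    grand = y.mean(axis=0)
    ssb = np.zeros(y.shape[1])
    ssw = np.zeros(y.shape[1])
    for lab in labels:
        rows = y[sites == lab]
        m = rows.mean(axis=0)
        ssb += rows.shape[0] * (m - grand) ** 2
        ssw += ((rows - m) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (len(labels) - 1)) / (ssw / (n - len(labels)))
    if np.isnan(f).any():
        warnings.warn("constant feature(s): F statistic is NaN",
                      RuntimeWarning, stacklevel=2)
    return f


def harmonize(dataset: MorphometryDataset, strategy: str,
              age_column: str = "age") -> MorphometryDataset:
    """Apply one of the named strategies and return the prepared dataset."""
    if strategy == "no_harmonization":
        return append_site_feature(dataset)
    if strategy == "combat_age_covariate":
        est = combat_fit(dataset, [age_column])
        return combat_apply(dataset, est)
    if strategy == "combat_no_covariate":
        est = combat_fit(dataset, None)
        return combat_apply(dataset, est)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
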