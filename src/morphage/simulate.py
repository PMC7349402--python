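"""Synthetic multi-site morphometry cohorts.

The generator draws data from the location/scale site-effect model the
harmonization step assumes: for subject j at site i and feature v,

    y_ijv = alpha_v + f_v(age_j) * beta_v + gamma_iv + delta_iv * eps_ijv

with additive site effects gamma ~ N(0, site_location_sd^2), multiplicative
effects delta log-normal with mean 1 (strictly positive), and Gaussian noise
eps. A configurable subset of features is age-informative through linear or
concave quadratic trajectories; all other features have beta_v = 0.

Defaults emulate the study cohort this package targets: 654 male subjects
(374 NC, 280 ASD) from 17 sites, ages ~6.5-39.4 with a young-skewed
distribution, and the full 1213-feature schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MorphometryDataset
from .schema import FeatureSchema, build_abide_schema

DEFAULT_AGE_RANGE = (6.47, 39.39)
DEFAULT_GROUP_PROPORTIONS = {"NC": 374 / 654, "ASD": 280 / 654}


def _even_site_sizes(n_total: int, n_sites: int) -> list[int]:
    base, extra = divmod(n_total, n_sites)
    return [base + (1 if i < extra else 0) for i in range(n_sites)]


@dataclass
class SyntheticConfig:
    """Generative settings for a multi-site cohort.

    ``age_range_per_site`` enables site-age confounding: giving sites
    disjoint or staggered age windows makes site membership informative
    about age, the situation in which covariate-blind harmonization is
    expected to destroy the age signal.
    """

    n_sites: int = 17
    subjects_per_site: list[int] | None = None
    age_range_per_site: list[tuple[float, float]] | None = None
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS))
    n_informative_features: int = 100
    trajectory: str = "mixed"  # linear | quadratic | mixed
    effect_size_scale: float = 1.0
    site_location_sd: float = 0.3
    site_scale_shape: float = 0.2
    noise_sd: float = 1.0
    icv_mean: float = 1.5e6
    icv_sd: float = 1.2e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_site is None:
            self.subjects_per_site = _even_site_sizes(654, self.n_sites)
        if self.age_range_per_site is None:
            self.age_range_per_site = [DEFAULT_AGE_RANGE] * self.n_sites
        if len(self.subjects_per_site) != self.n_sites:
            raise ValueError("subjects_per_site length must equal n_sites")
        if len(self.age_range_per_site) != self.n_sites:
            raise ValueError("age_range_per_site length must equal n_sites")
        for lo, hi in self.age_range_per_site:
            if not (0 < lo < hi):
                raise ValueError(f"invalid age range ({lo}, {hi})")
        if self.trajectory not in ("linear", "quadratic", "mixed"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a simulated dataset, for recovery tests."""

    alpha: np.ndarray          # (P,) feature intercepts
    beta: np.ndarray           # (P,) age-effect sizes, 0 for uninformative
    informative: np.ndarray    # (P,) boolean mask
    trajectory: list[str]      # per-feature "none" | "linear" | "quadratic"
    gamma: np.ndarray          # (S, P) additive site effects
    delta: np.ndarray          # (S, P) multiplicative site effects, > 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "informative": self.informative.astype(int).tolist(),
            "trajectory": self.trajectory,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def simulate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the subject table: ages, groups, sites and ICV.

    Ages within each site's window follow a Beta(1.5, 3.5) shape, which
    skews young (sample mean near one third of the window), matching
    developmental cohorts. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    groups = sorted(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in groups])
    rows = []
    idx = 0
    for site, (n_s, (lo, hi)) in enumerate(
            zip(config.subjects_per_site, config.age_range_per_site), start=1):
        ages = lo + (hi - lo) * rng.beta(1.5, 3.5, size=n_s)
        labels = rng.choice(groups, size=n_s, p=probs)
        icv = np.abs(rng.normal(config.icv_mean, config.icv_sd, size=n_s))
        for a, g, v in zip(ages, labels, icv):
            idx += 1
            rows.append((f"sub-{idx:04d}", float(a), str(g), site, float(v)))
    subjects = pd.DataFrame(rows, columns=["subject_id", "age", "group",
                                           "site", "icv"])
    return subjects.set_index("subject_id")


def _standardized(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def simulate_features(
    cohort: pd.DataFrame,
    schema: FeatureSchema | None = None,
    config: SyntheticConfig | None = None,
    gamma: np.ndarray | None = None,
    delta: np.ndarray | None = None,
) -> tuple[MorphometryDataset, SimulationTruth]:
    """Draw feature values for a cohort under the location/scale model.

    ``gamma`` / ``delta`` override the drawn site effects (shape (S, P));
    they are recorded in the returned truth either way. Trajectories are
    standardized to zero mean / unit variance over the cohort so that
    ``beta`` is an effect size in noise-sd units when ``noise_sd=1``.
    """
    config = config or SyntheticConfig()
    schema = schema or build_abide_schema()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, p, s = len(cohort), len(schema), config.n_sites
    age = cohort["age"].to_numpy(float)
    site_idx = cohort["site"].to_numpy(int) - 1
    if site_idx.min() < 0 or site_idx.max() >= s:
        raise ValueError("cohort site labels outside 1..n_sites")
    if config.n_informative_features > p:
        raise ValueError("more informative features than features")

    alpha = rng.normal(0.0, 1.0, size=p)
    beta = np.zeros(p)
    informative = np.zeros(p, dtype=bool)
    info_idx = rng.choice(p, size=config.n_informative_features, replace=False)
    informative[info_idx] = True
    beta[info_idx] = (config.effect_size_scale
                      * rng.uniform(0.4, 1.0, size=len(info_idx))
                      * rng.choice([-1.0, 1.0], size=len(info_idx)))

    trajectory = ["none"] * p
    lo = min(r[0] for r in config.age_range_per_site)
    hi = max(r[1] for r in config.age_range_per_site)
    signal = np.zeros((n, p))
    lin = _standardized(age)
    for j_pos, j in enumerate(info_idx):
        if config.trajectory == "linear":
            kind = "linear"
        elif config.trajectory == "quadratic":
            kind = "quadratic"
        else:
            kind = "linear" if j_pos % 2 == 0 else "quadratic"
        trajectory[j] = kind
        if kind == "linear":
            f = lin
        else:
            # concave trajectory peaking in the upper half of the age range
            peak = rng.uniform((lo + hi) / 2, hi)
            f = _standardized(-((age - peak) / (hi - lo)) ** 2)
        signal[:, j] = f * beta[j]

    if gamma is None:
        gamma = rng.normal(0.0, config.site_location_sd, size=(s, p))
    if delta is None:
        shape = config.site_scale_shape
        delta = rng.lognormal(mean=-shape ** 2 / 2, sigma=shape, size=(s, p))
    gamma = np.asarray(gamma, float)
    delta = np.asarray(delta, float)
    if gamma.shape != (s, p) or delta.shape != (s, p):
        raise ValueError("gamma/delta must have shape (n_sites, n_features)")
    if (delta <= 0).any():
        raise ValueError("delta must be strictly positive")

    eps = rng.normal(0.0, 1.0, size=(n, p)) * config.noise_sd
    values = alpha + signal + gamma[site_idx] + delta[site_idx] * eps
    dataset = MorphometryDataset(
        cohort.copy(),
        pd.DataFrame(values, index=cohort.index, columns=schema.feature_ids),
        schema,
    )
    truth = SimulationTruth(alpha, beta, informative, trajectory, gamma, delta)
    return dataset, truth


def simulate_dataset(
    config: SyntheticConfig, schema: FeatureSchema | None = None
) -> tuple[MorphometryDataset, SimulationTruth]:
    """Convenience wrapper: cohort + features in one call."""
    cohort = simulate_cohort(config)
    return simulate_features(cohort, schema, config)


def confounded_age_ranges(
    n_sites: int,
    age_min: float = DEFAULT_AGE_RANGE[0],
    age_max: float = DEFAULT_AGE_RANGE[1],
    overlap: float = 0.25,
) -> list[tuple[float, float]]:
    """Staggered per-site age windows inducing site-age confounding.

    The full range is split into ``n_sites`` consecutive windows widened by
    ``overlap`` of a window on each side, so neighbouring sites share some
    ages but site membership strongly predicts age.
    """
    width = (age_max - age_min) / n_sites
    ranges = []
    for i in range(n_sites):
        lo = max(age_min, age_min + (i - overlap) * width)
        hi = min(age_max, age_min + (i + 1 + overlap) * width)
        ranges.append((lo, hi))
    return ranges
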