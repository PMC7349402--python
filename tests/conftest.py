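"""Shared fixtures: compact schemas and simulated multi-site datasets."""

from __future__ import annotations

import numpy as np
import pytest

from morphage.schema import FeatureSchema, build_generic_schema
from morphage.simulate import SyntheticConfig, confounded_age_ranges, simulate_features, simulate_cohort


def make_flat_schema(p: int, n_regions: int = 10) -> FeatureSchema:
    """A p-feature schema with generic cortical regions, for tests that do
    not need the full 1213-feature layout."""
    return build_generic_schema(p, n_regions)


@pytest.fixture(scope="session")
def schema200() -> FeatureSchema:
    return make_flat_schema(200, n_regions=20)


@pytest.fixture(scope="session")
def schema100() -> FeatureSchema:
    return make_flat_schema(100, n_regions=10)


def simulate_sites(schema, *, n_sites=4, per_site=50, n_informative=40,
                   gamma_sd=0.3, delta_shape=0.2, noise_sd=1.0, seed=7,
                   age_ranges=None, trajectory="mixed", gamma=None, delta=None,
                   effect=1.0):
    """One-stop simulated dataset for harmonization/regression tests."""
    config = SyntheticConfig(
        n_sites=n_sites,
        subjects_per_site=[per_site] * n_sites if isinstance(per_site, int)
        else list(per_site),
        age_range_per_site=age_ranges or [(6.47, 39.39)] * n_sites,
        n_informative_features=n_informative,
        trajectory=trajectory,
        effect_size_scale=effect,
        site_location_sd=gamma_sd,
        site_scale_shape=delta_shape,
        noise_sd=noise_sd,
        seed=seed,
    )
    cohort = simulate_cohort(config)
    dataset, truth = simulate_features(cohort, schema, config,
                                       gamma=gamma, delta=delta)
    return dataset, truth, config


@pytest.fixture(scope="session")
def combat_recovery_data(schema200):
    """Location/scale simulation with known site effects (S=4, n=50/site,
    P=200) used by the ComBat recovery checks."""
    return simulate_sites(schema200, n_sites=4, per_site=50, n_informative=40,
                          gamma_sd=0.3, delta_shape=0.2, seed=7)


@pytest.fixture(scope="session")
def confounded_data(schema200):
    """Site-age confounded cohort: 17 sites with staggered age windows,
    N=300, 30 linear informative features of 200."""
    sizes = [18] * 11 + [17] * 6
    return simulate_sites(
        schema200, n_sites=17, per_site=sizes, n_informative=30,
        gamma_sd=0.2, delta_shape=0.15, seed=5, trajectory="linear",
        age_ranges=confounded_age_ranges(17, overlap=2.5))


def age_feature_correlations(dataset) -> np.ndarray:
    """Pearson correlation of every feature with age."""
    v = dataset.matrix()
    a = dataset.ages
    a = (a - a.mean()) / a.std()
    vv = (v - v.mean(axis=0)) / v.std(axis=0)
    return (vv * a[:, None]).mean(axis=0)
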