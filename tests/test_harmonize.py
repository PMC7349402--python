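"""Harmonization strategies: site feature, OLS residualization, ComBat."""

import numpy as np
import pytest

from morphage.harmonize import (append_site_feature, combat_apply, combat_fit,
                                harmonize, residualize_site_ols,
                                site_effect_statistic)

from conftest import age_feature_correlations, make_flat_schema, simulate_sites


class TestAppendSiteFeature:
    def test_adds_one_column(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=3, per_site=5,
                                  n_informative=5, seed=1)
        out = append_site_feature(ds)
        assert out.n_features == ds.n_features + 1
        assert out.schema.category_of("site_code") == "global"

    def test_encoding_is_offset_from_baseline(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=3, per_site=4,
                                  n_informative=5, seed=2)
        out = append_site_feature(ds)
        code = out.values["site_code"].to_numpy()
        np.testing.assert_array_equal(code, ds.sites - 1)

    def test_single_site_codes_to_zero(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=1, per_site=6,
                                  n_informative=5, seed=3)
        out = append_site_feature(ds)
        assert (out.values["site_code"] == 0).all()


class TestResidualizeSiteOLS:
    def test_pure_location_shift_removed(self, schema100):
        gamma = np.zeros((2, 100))
        gamma[1, :] = 3.0
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=500,
                                  n_informative=0, gamma=gamma,
                                  delta=np.ones((2, 100)), seed=4)
        out = residualize_site_ols(ds)
        v = out.matrix()
        sites = ds.sites
        diff = v[sites == 2].mean(axis=0) - v[sites == 1].mean(axis=0)
        assert np.abs(diff).max() < 1e-10  # OLS removes fitted means exactly

    def test_covariate_contribution_retained(self, schema100):
        # age effect, no site effect, no noise: output approximately input
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=100,
                                  n_informative=100, noise_sd=1e-6,
                                  gamma=np.zeros((2, 100)),
                                  delta=np.ones((2, 100)),
                                  trajectory="linear", seed=5)
        out = residualize_site_ols(ds, ["age"])
        assert np.abs(out.matrix() - ds.matrix()).max() < 1e-3

    def test_site_centered_data_unchanged(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=50,
                                  n_informative=0, seed=6)
        centered = ds.matrix().copy()
        for s in (1, 2):
            rows = ds.sites == s
            centered[rows] -= centered[rows].mean(axis=0)
        cds = ds.with_values(centered)
        out = residualize_site_ols(cds)
        np.testing.assert_allclose(out.matrix(), centered, atol=1e-10)

    def test_single_site_rejected(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=1, per_site=10,
                                  n_informative=0, seed=7)
        with pytest.raises(ValueError):
            residualize_site_ols(ds)


class TestCombatFit:
    def test_no_shrinkage_limit_matches_site_means(self, schema100):
        # eb=False returns the per-site least-squares estimates exactly
        ds, _, _ = simulate_sites(schema100, n_sites=3, per_site=30,
                                  n_informative=0, seed=8)
        est = combat_fit(ds, None, eb=False)
        y = ds.matrix()
        sites = ds.sites
        for i, lab in enumerate(est.site_labels):
            expected = ((y[sites == lab] - est.alpha) / est.pooled_sd).mean(axis=0)
            np.testing.assert_allclose(est.gamma_star[i], expected, atol=1e-12)

    def test_eb_beats_no_pooling_on_known_effects(self, combat_recovery_data):
        ds, truth, cfg = combat_recovery_data
        est = combat_fit(ds, ["age"])
        n_i = np.array(cfg.subjects_per_site, float)
        centered_truth = truth.gamma - (n_i / n_i.sum()) @ truth.gamma
        eb_gamma = est.gamma_star * est.pooled_sd
        # no-pooling oracle: per-site means of residuals after alpha + W beta
        w = ds.subjects[["age"]].to_numpy(float)
        resid = ds.matrix() - est.alpha - w @ est.beta
        sites = ds.sites
        np_gamma = np.vstack([resid[sites == s].mean(axis=0)
                              for s in est.site_labels])
        assert (np.abs(eb_gamma - centered_truth).mean()
                < np.abs(np_gamma - centered_truth).mean())

    def test_covariate_slope_recovered(self, schema100):
        ds, truth, _ = simulate_sites(schema100, n_sites=2, per_site=200,
                                      n_informative=100, noise_sd=1e-6,
                                      gamma=np.zeros((2, 100)),
                                      delta=np.ones((2, 100)),
                                      trajectory="linear", seed=9)
        est = combat_fit(ds, ["age"])
        true_slope = truth.beta / ds.ages.std()
        np.testing.assert_allclose(est.beta[0], true_slope, atol=1e-4)

    def test_small_site_rejected(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=10,
                                  n_informative=0, seed=10)
        tiny = ds.with_values(ds.matrix())
        keep = np.ones(ds.n_subjects, dtype=bool)
        keep[np.where(ds.sites == 2)[0][1:]] = False  # site 2 -> 1 subject
        sub = type(ds)(ds.subjects.loc[keep].copy(), ds.values.loc[keep].copy(),
                       ds.schema)
        with pytest.raises(ValueError, match="2"):
            combat_fit(sub)

    def test_zero_variance_feature_named(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=10,
                                  n_informative=0, seed=11)
        v = ds.matrix()
        v[:, 3] = 7.0
        with pytest.raises(ValueError, match="f3"):
            combat_fit(ds.with_values(v))


class TestCombatApply:
    def test_single_site_identity(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=1, per_site=40,
                                  n_informative=5, seed=12)
        out = combat_apply(ds, combat_fit(ds, None, eb=False))
        np.testing.assert_allclose(out.matrix(), ds.matrix(), atol=1e-9)

    def test_site_f_statistic_drops(self, combat_recovery_data):
        ds, _, _ = combat_recovery_data
        f_pre = site_effect_statistic(ds)
        out = combat_apply(ds, combat_fit(ds, ["age"]))
        f_post = site_effect_statistic(out)
        assert (f_post < f_pre).mean() >= 0.95

    def test_direct_mode_idempotent(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=3, per_site=40,
                                  n_informative=0, seed=13)
        h1 = combat_apply(ds, combat_fit(ds, None, eb=False))
        h2 = combat_apply(h1, combat_fit(h1, None, eb=False))
        rms = np.sqrt(np.mean((h2.matrix() - h1.matrix()) ** 2))
        assert rms < 1e-6

    def test_eb_second_pass_nearly_inert(self, combat_recovery_data):
        ds, _, _ = combat_recovery_data
        h1 = combat_apply(ds, combat_fit(ds, None))
        h2 = combat_apply(h1, combat_fit(h1, None))
        first = np.sqrt(np.mean((h1.matrix() - ds.matrix()) ** 2))
        second = np.sqrt(np.mean((h2.matrix() - h1.matrix()) ** 2))
        assert second < 0.1 * first

    def test_unknown_site_rejected(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=20,
                                  n_informative=0, seed=14)
        est = combat_fit(ds, None)
        other = ds.with_values(ds.matrix())
        other.subjects["site"] = other.subjects["site"].replace({2: 9})
        with pytest.raises(ValueError, match="site"):
            combat_apply(other, est)

    def test_matches_ols_residualization_without_shrinkage(self, schema100):
        # direct-mode ComBat with unit scale equals OLS residualization up
        # to a per-feature constant (reference-site vs grand-mean centring)
        ds, _, _ = simulate_sites(schema100, n_sites=3, per_site=40,
                                  n_informative=0, seed=15)
        est = combat_fit(ds, None, eb=False)
        est.delta_star = np.ones_like(est.delta_star)
        cb = combat_apply(ds, est).matrix()
        ols = residualize_site_ols(ds).matrix()
        diff = cb - ols
        assert np.abs(diff - diff.mean(axis=0)).max() < 1e-8


class TestCovariatePreservation:
    def test_with_covariate_preserves_age_association(self, confounded_data):
        ds, truth, _ = confounded_data
        pre = age_feature_correlations(ds)
        out = combat_apply(ds, combat_fit(ds, ["age"]))
        post = age_feature_correlations(out)
        inf = truth.informative
        assert abs(np.mean(np.abs(post[inf]) - np.abs(pre[inf]))) < 0.05

    def test_without_covariate_attenuates_age_association(self, confounded_data):
        ds, truth, _ = confounded_data
        pre = age_feature_correlations(ds)
        out = combat_apply(ds, combat_fit(ds, None))
        post = age_feature_correlations(out)
        inf = truth.informative
        assert np.mean(np.abs(pre[inf]) - np.abs(post[inf])) > 0.10


class TestSiteEffectStatistic:
    def test_null_distribution_near_one(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=4, per_site=100,
                                  n_informative=0,
                                  gamma=np.zeros((4, 100)),
                                  delta=np.ones((4, 100)), seed=16)
        f = site_effect_statistic(ds)
        assert abs(f.mean() - 1.0) < 0.25

    def test_large_shift_detected(self, schema100):
        gamma = np.zeros((2, 100))
        gamma[1, :] = 2.0
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=100,
                                  n_informative=0, gamma=gamma,
                                  delta=np.ones((2, 100)), seed=17)
        assert site_effect_statistic(ds).min() > 10

    def test_constant_feature_flagged(self, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=10,
                                  n_informative=0, seed=18)
        v = ds.matrix()
        v[:, 0] = 1.0
        with pytest.warns(RuntimeWarning):
            f = site_effect_statistic(ds.with_values(v))
        assert np.isnan(f[0])

    def test_estimates_json_round_trip(self, tmp_path, schema100):
        ds, _, _ = simulate_sites(schema100, n_sites=2, per_site=20,
                                  n_informative=5, seed=19)
        est = combat_fit(ds, ["age"])
        est.to_json(tmp_path / "est.json")
        from morphage.harmonize import SiteEffectEstimates
        back = SiteEffectEstimates.from_json(tmp_path / "est.json")
        np.testing.assert_allclose(back.gamma_star, est.gamma_star)
        out_a = combat_apply(ds, est).matrix()
        out_b = combat_apply(ds, back).matrix()
        np.testing.assert_allclose(out_a, out_b)


def test_harmonize_dispatcher_strategies(schema100):
    ds, _, _ = simulate_sites(schema100, n_sites=3, per_site=20,
                              n_informative=5, seed=20)
    assert harmonize(ds, "no_harmonization").n_features == 101
    assert harmonize(ds, "combat_age_covariate").n_features == 100
    with pytest.raises(ValueError):
        harmonize(ds, "unknown")
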