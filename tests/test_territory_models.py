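import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdhscape import (
    SimConfig,
    fit_dispersion_model,
    fit_group_glm,
    fit_logdistance_lm,
    fit_null_glm,
    fit_seasonal_glmm,
    fit_territory_glm,
    gen_metric_panel,
    gen_territory_panel,
    lr_test,
    metrics_frame,
)
from rdhscape.metrics import SEASONS
from rdhscape.territory_models import TERRITORY_SIZE_TERMS

import oracles


@pytest.fixture(scope="module")
def panel():
    return metrics_frame(gen_territory_panel(SimConfig(seed=17)))


class TestTerritoryGLM:
    def test_recovers_generating_signs(self, panel):
        fit = fit_territory_glm(panel)
        assert fit.coef("heterogeneity") > 0
        assert fit.coef("patch_richness") > 0
        assert fit.coef("mf_ratio") > 0
        assert fit.coef("dispersion") > 0
        assert set(fit.terms) == {"Intercept", *TERRITORY_SIZE_TERMS}

    def test_constant_predictors_reduce_to_intercept_only(self, panel):
        df = panel.copy()
        for c in TERRITORY_SIZE_TERMS:
            df[c] = 1.0
        fit = fit_territory_glm(df)
        assert fit.terms == ["Intercept"]
        # intercept-only Gamma MLE is the log of the sample mean
        assert fit.coef("Intercept") == pytest.approx(
            np.log(df.territory_area.mean()), abs=1e-8
        )

    def test_deviance_never_increases_with_added_predictor(self, panel):
        from rdhscape.census_models import fit_gamma_glm

        df = panel.dropna()
        y = df.territory_area.to_numpy(float)
        X1 = pd.DataFrame({"Intercept": np.ones(len(df)), "dispersion": df.dispersion})
        X2 = X1.assign(patch_richness=df.patch_richness)
        X3 = X2.assign(heterogeneity=df.heterogeneity)
        devs = [fit_gamma_glm(y, X).deviance for X in (X1, X2, X3)]
        assert devs[0] >= devs[1] >= devs[2]

    def test_group_size_scaling_equivariance(self, panel):
        fit1 = fit_group_glm(panel)
        scaled = panel.assign(n_adults=panel.n_adults * 3.0)
        fit2 = fit_group_glm(scaled)
        assert fit2.coef("Intercept") - fit1.coef("Intercept") == pytest.approx(
            np.log(3.0), abs=1e-6
        )
        np.testing.assert_allclose(fit2.params[1:], fit1.params[1:], atol=1e-6)


class TestLRTest:
    def test_full_equals_null(self, panel):
        null = fit_null_glm(panel.dropna(), "territory_area")
        res = lr_test(null, null)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_statistic_matches_density_oracle_small_n(self, rng):
        from rdhscape.census_models import fit_gamma_glm

        n = 10
        x = rng.uniform(0, 3, n)
        y = rng.gamma(2.0, np.exp(0.4 + 0.3 * x) / 2.0)
        Xf = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        Xn = pd.DataFrame({"Intercept": np.ones(n)})
        full = fit_gamma_glm(y, Xf)
        null = fit_gamma_glm(y, Xn)
        res = lr_test(full, null)
        # deviance drop equals twice the unit-shape log-density difference
        ll_full = oracles.gamma_loglik(y, np.exp(Xf.to_numpy() @ full.params), 1.0)
        ll_null = oracles.gamma_loglik(y, np.exp(Xn.to_numpy() @ null.params), 1.0)
        assert res.statistic == pytest.approx(2.0 * (ll_full - ll_null), rel=1e-8)
        assert res.df == 1

    def test_p_monotone_in_statistic(self):
        ps = [stats.chi2.sf(s, 5) for s in (1.0, 5.0, 10.0, 20.0)]
        from rdhscape.fits import LRTResult

        results = [LRTResult.from_loglik(s / 2, 0.0, 5, 0, 0) for s in (1.0, 5.0, 10.0, 20.0)]
        for r, p in zip(results, ps):
            assert r.pvalue == pytest.approx(p)
        assert all(a.pvalue > b.pvalue for a, b in zip(results, results[1:]))

    def test_type_i_error_of_group_size_lrt(self):
        """Under an intercept-only truth, the 5-df LR test of the group-size
        model rejects at close to the nominal 5% rate."""
        from rdhscape.census_models import fit_gamma_glm

        rng = np.random.default_rng(31)
        n = 84
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            covs = rng.normal(0, 1, (n, 5))
            y = rng.gamma(4.0, np.exp(1.776) / 4.0, n)
            X = pd.DataFrame(covs, columns=["a", "b", "c", "d", "e"])
            X.insert(0, "Intercept", 1.0)
            full = fit_gamma_glm(y, X)
            null = fit_gamma_glm(y, X[["Intercept"]])
            rejections += lr_test(full, null).pvalue < 0.05
        # binomial 99.9% band around 0.05 with 400 draws
        assert 0.014 <= rejections / n_rep <= 0.086


class TestSeasonalGLMM:
    def test_post_mating_contraction_detected(self):
        """A -0.08 post-mating log-effect with group SD 0.4 is recovered as
        a negative, significant contrast in most replicates."""
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            df = gen_metric_panel(
                36, seed=500 + rep, intercept=0.6,
                season_effects={"pre_mating": 0.0, "mating": 0.0, "post_mating": -0.08},
                group_sd=0.4, dispersion_by_season={s: 0.012 for s in SEASONS},
                response="territory_area",
            )
            fit = fit_seasonal_glmm(df, "territory_area")
            i = fit.terms.index("season[post_mating]")
            if fit.params[i] < 0 and fit.pvalues[i] < 0.05:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_reference_level_is_mating(self, panel):
        fit = fit_seasonal_glmm(panel, "territory_area", se=False)
        assert set(fit.terms) == {"Intercept", "season[pre_mating]", "season[post_mating]"}


class TestDispersionSubmodel:
    def test_seasonal_model_never_fits_worse(self):
        for seed in (1, 2, 3):
            df = gen_metric_panel(20, seed=seed, group_sd=0.3)
            const, seasonal, res = fit_dispersion_model(df, se=False)
            assert seasonal.loglik >= const.loglik - 1e-6
            assert res.df == 2
            assert res.statistic >= 0

    def test_tenfold_contrast_detected(self):
        rejections = 0
        for rep in range(10):
            df = gen_metric_panel(
                36, seed=900 + rep, group_sd=0.4,
                dispersion_by_season={
                    "pre_mating": 0.1, "mating": 0.1, "post_mating": 0.01},
            )
            _, seasonal, res = fit_dispersion_model(df, se=False)
            rejections += res.pvalue < 0.05
        assert rejections >= 9
        # the detected direction: lower dispersion post-mating
        i = seasonal.disp_terms.index("season[post_mating]")
        assert seasonal.disp_params[i] < 0


class TestLogDistanceLM:
    def test_response_scaling_shifts_only_intercept(self, panel):
        fit1 = fit_logdistance_lm(panel)
        fit2 = fit_logdistance_lm(panel.assign(dispersion=panel.dispersion * 5.0))
        assert fit2.coef("Intercept") - fit1.coef("Intercept") == pytest.approx(
            np.log(5.0), abs=1e-10
        )
        np.testing.assert_allclose(fit2.params[1:], fit1.params[1:], atol=1e-10)
        assert fit2.extra["r_squared"] == pytest.approx(fit1.extra["r_squared"], abs=1e-10)

    def test_f_pvalue_uniform_under_equal_season_means(self):
        rng = np.random.default_rng(55)
        pvals = []
        for _ in range(300):
            df = pd.DataFrame({
                "group_id": np.repeat([f"g{i}" for i in range(28)], 3),
                "season": list(SEASONS) * 28,
                "dispersion": rng.lognormal(4.0, 0.5, 84),
            })
            pvals.append(fit_logdistance_lm(df).extra["f_pvalue"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_reports_f_with_correct_df(self, panel):
        fit = fit_logdistance_lm(panel)
        assert fit.extra["f_df"] == (2, fit.n_used - 3)
        assert 0.0 <= fit.extra["r_squared"] <= 1.0
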