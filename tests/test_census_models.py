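import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdhscape import (
    ModelFit,
    PowerSpec,
    SimConfig,
    auc_to_cliffs,
    combined_slope,
    d_for_power,
    d_to_auc,
    fit_census_glm,
    fit_gamma_glm,
    gen_census,
    rank_sum_test,
    two_sample_power,
)
from rdhscape.census_models import census_frame

import oracles


class TestRankSumTest:
    def test_fully_separated_small_samples_exact(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.u == 0.0
        assert res.w == 6.0  # rank sum of first sample: 1+2+3
        assert res.pvalue == pytest.approx(0.1)  # 2/20 orderings

    def test_identical_samples_p_is_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0, 4.0] * 3, [1.0, 2.0, 3.0, 4.0] * 3)
        assert res.pvalue == pytest.approx(1.0)

    def test_swap_duality(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 20)
        a = rank_sum_test(x, y)
        b = rank_sum_test(y, x)
        assert a.u + b.u == pytest.approx(15 * 20)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestCensusGLM:
    def test_group_means_closed_form(self):
        # saturated two-group design: intercept log(a), indicator log(b/a)
        y = np.array([2.0, 2.0, 2.0, 6.0, 6.0, 6.0])
        X = pd.DataFrame({"Intercept": 1.0, "urban": [0, 0, 0, 1, 1, 1]})
        fit = fit_gamma_glm(y, X)
        assert fit.coef("Intercept") == pytest.approx(np.log(2.0), abs=1e-8)
        assert fit.coef("urban") == pytest.approx(np.log(3.0), abs=1e-8)

    def test_rate_ratio_is_exp_of_estimate(self):
        cfg = SimConfig(seed=3, n_rural=30, n_urban=30)
        fit = fit_census_glm(gen_census(cfg))
        np.testing.assert_allclose(fit.rate_ratios, np.exp(fit.params), rtol=1e-12)
        ci = fit.rr_conf_int
        assert np.all(ci[:, 0] < fit.rate_ratios)
        assert np.all(fit.rate_ratios < ci[:, 1])
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (len(fit.terms) + 1), rel=1e-9)

    def test_parameter_recovery_coverage(self):
        """Refitting data generated under the interaction truth covers each
        coefficient with its 95% Wald interval at close to nominal rate."""
        truth = np.array([-0.346, 0.110, 1.169, -0.106])
        hits = np.zeros(4)
        n_rep = 40
        for rep in range(n_rep):
            cfg = SimConfig(seed=1000 + rep, n_rural=130, n_urban=120)
            fit = fit_census_glm(gen_census(cfg))
            lo = fit.params - 1.96 * fit.bse
            hi = fit.params + 1.96 * fit.bse
            hits += (lo <= truth) & (truth <= hi)
        assert np.all(hits >= 0.825 * n_rep)  # 3.6 sigma below nominal 95%

    def test_zero_density_sites_dropped_with_count(self):
        cfg = SimConfig(seed=5, n_rural=40, n_urban=40)
        sites = gen_census(cfg)
        n_zero = sum(1 for s in sites if s.dog_count == 0)
        fit = fit_census_glm(sites)
        assert fit.n_dropped == n_zero
        assert fit.n_used == len(sites) - n_zero

    def test_wald_pvalues_uniform_under_null(self):
        """With no resource effect in truth, resource-term p-values are
        uniform across simulated refits."""
        rng = np.random.default_rng(99)
        n = 93
        pvals = []
        for _ in range(400):
            res_density = rng.gamma(1.2, 4.0, n)
            urban = (np.arange(n) < 41).astype(float)
            mu = np.exp(-0.3 + 1.2 * urban)  # beta1 = beta3 = 0
            y = rng.gamma(3.0, mu / 3.0)
            X = pd.DataFrame(
                {"Intercept": 1.0, "resource_density": res_density, "urban": urban,
                 "resource_density:urban": res_density * urban}
            )
            fit = fit_gamma_glm(y, X)
            pvals.append(fit.pvalues[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCombinedSlope:
    @staticmethod
    def _fit_with(params, cov):
        k = len(params)
        return ModelFit(
            terms=["Intercept", "resource_density", "urban", "resource_density:urban"],
            params=np.asarray(params, float), bse=np.sqrt(np.diag(cov)),
            cov_params=np.asarray(cov, float), df_resid=89, loglik=0.0,
            deviance=0.0, null_deviance=0.0, aic=0.0, dispersion=1.0, n_used=93,
        )

    def test_zero_interaction_returns_rural_slope(self):
        cov = np.diag([0.1, 0.02, 0.1, 0.02]) ** 2
        fit = self._fit_with([-0.3, 0.12, 1.1, 0.0], cov)
        slope, _ = combined_slope(fit, "urban")
        assert slope == pytest.approx(0.12)

    def test_published_style_flat_urban_slope(self):
        cov = np.diag([0.128, 0.019, 0.206, 0.022]) ** 2
        fit = self._fit_with([-0.346, 0.109, 1.169, -0.106], cov)
        slope, se = combined_slope(fit, "urban")
        assert slope == pytest.approx(0.003, abs=1e-12)
        assert se == pytest.approx(np.hypot(0.019, 0.022))

    def test_matches_simulation_delta_method(self, rng):
        cfg = SimConfig(seed=21, n_rural=60, n_urban=60)
        fit = fit_census_glm(gen_census(cfg))
        slope, se = combined_slope(fit, "urban")
        # delta-method oracle: draw from the coefficient sampling distribution
        draws = rng.multivariate_normal(fit.params, fit.cov_params, 200_000)
        sums = draws[:, 1] + draws[:, 3]
        assert slope == pytest.approx(fit.params[1] + fit.params[3], rel=1e-12)
        assert se == pytest.approx(sums.std(), rel=0.02)


class TestPowerAnalysis:
    def test_null_effect_gives_alpha(self):
        assert two_sample_power(PowerSpec(52, 41, 0.05, 0.0)) == pytest.approx(0.05, abs=1e-9)

    def test_realized_design_power(self):
        assert two_sample_power(PowerSpec(52, 41, 0.05, 0.6)) == pytest.approx(0.81, abs=0.01)

    def test_monotone_in_d_and_n(self):
        powers_d = [two_sample_power(PowerSpec(52, 41, 0.05, d)) for d in (0.2, 0.4, 0.6, 0.8)]
        assert all(a < b for a, b in zip(powers_d, powers_d[1:]))
        powers_n = [two_sample_power(PowerSpec(n, 41, 0.05, 0.5)) for n in (10, 30, 60, 120)]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))

    def test_d_for_power_round_trip(self):
        for target in (0.3, 0.5, 0.8, 0.95):
            d = d_for_power(target, 52, 41)
            assert two_sample_power(PowerSpec(52, 41, 0.05, d)) == pytest.approx(target, abs=1e-8)
        d0 = d_for_power(0.0500001, 52, 41)
        assert d0 == pytest.approx(0.0, abs=1e-2)

    def test_normal_shift_equivalents(self):
        assert d_to_auc(0.0) == pytest.approx(0.5)
        assert auc_to_cliffs(0.5) == 0.0
        d = d_for_power(0.80, 52, 41, 0.05)
        auc = d_to_auc(d)
        assert auc == pytest.approx(0.662, abs=0.002)
        assert auc_to_cliffs(round(auc, 3)) == pytest.approx(0.324)


class TestGLMOracle:
    def test_fit_matches_direct_density_ml(self, rng):
        """The GLM fit agrees with an IRLS-free direct log-density maximizer."""
        for n in (20, 50):
            x1 = rng.uniform(0, 5, n)
            x2 = rng.uniform(0, 1, n)
            mu = np.exp(0.3 + 0.25 * x1 - 0.6 * x2)
            y = rng.gamma(4.0, mu / 4.0)
            X = pd.DataFrame({"Intercept": 1.0, "x1": x1, "x2": x2})
            fit = fit_gamma_glm(y, X)
            beta_ml, shape_ml, ll = oracles.direct_ml_gamma_glm(y, X)
            np.testing.assert_allclose(fit.params, beta_ml, rtol=1e-5)

    def test_deviance_matches_density_oracle_small_n(self, rng):
        """Fit deviance equals -2*(loglik - saturated loglik) evaluated by
        direct density computation at unit shape."""
        n = 10
        x = rng.uniform(0, 4, n)
        y = rng.gamma(2.0, np.exp(0.5 + 0.2 * x) / 2.0)
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        fit = fit_gamma_glm(y, X)
        eta = X.to_numpy() @ fit.params
        ll_fit = oracles.gamma_loglik(y, np.exp(eta), 1.0)
        ll_sat = oracles.gamma_loglik(y, y, 1.0)
        assert fit.deviance == pytest.approx(-2.0 * (ll_fit - ll_sat), rel=1e-8)


def test_census_frame_columns():
    cfg = SimConfig(seed=2, n_rural=8, n_urban=8, area_range_ha=(5.0, 40.0))
    df = census_frame(gen_census(cfg))
    assert len(df) == 16
    assert {"dog_density", "resource_density", "settlement", "area_ha"} <= set(df.columns)
    assert (df.area_ha > 0).all()
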