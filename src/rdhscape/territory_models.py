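"""Territory-scale inference.

Fixed-effects Gamma GLMs relate territory size and adult group size to the
resource metrics (heterogeneity, patch richness, dispersion) and group
composition; likelihood-ratio tests compare each to its intercept-only
counterpart.  Seasonal questions use Gamma GLMMs with a group random
intercept (mating season as the reference level, so contrasts are
post-vs-mating and pre-vs-mating).  For resource heterogeneity a
season-specific dispersion submodel is compared against constant dispersion
by a 2-df LRT; for the mean inter-patch distance, whose random-intercept
fits are prone to singularity, a simple linear model on the log response is
used instead.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .census_models import fit_gamma_glm
from .fits import LRTResult, ModelFit
from .glmm import SINGULAR_SD, MixedFit, fit_gamma_glmm
from .metrics import SEASONS, TerritoryRecord, metrics_frame

__all__ = [
    "TERRITORY_SIZE_TERMS",
    "GROUP_SIZE_TERMS",
    "fit_territory_glm",
    "fit_group_glm",
    "lr_test",
    "fit_seasonal_glmm",
    "fit_dispersion_model",
    "fit_logdistance_lm",
]

logger = logging.getLogger(__name__)

TERRITORY_SIZE_TERMS = [
    "n_adults", "heterogeneity", "patch_richness", "mf_ratio", "dispersion",
]
GROUP_SIZE_TERMS = [
    "heterogeneity", "patch_richness", "mf_ratio", "dispersion", "territory_area",
]


def _as_frame(rows: Union[pd.DataFrame, Sequence[TerritoryRecord]]) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return metrics_frame(rows)


def _design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for t in terms:
        X[t] = pd.to_numeric(df[t], errors="coerce")
    return X


def _drop_constant_predictors(X: pd.DataFrame) -> pd.DataFrame:
    """Degenerate designs (a predictor without variation) reduce gracefully."""
    keep = ["Intercept"] + [
        c for c in X.columns if c != "Intercept" and np.nanstd(X[c].to_numpy(float)) > 0
    ]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant predictor(s): %s", ", ".join(dropped))
    return X[keep]


def fit_territory_glm(rows, min_rows: int = 10) -> ModelFit:
    """Territory size (ha) ~ group size + heterogeneity + richness +
    male:female ratio + dispersion, Gamma GLM with log link."""
    df = _as_frame(rows)
    X = _drop_constant_predictors(_design(df, TERRITORY_SIZE_TERMS))
    y = df["territory_area"].to_numpy(float)
    if int(np.sum(np.isfinite(y) & (y > 0))) < min_rows:
        raise ValueError(f"need >= {min_rows} complete rows")
    fit = fit_gamma_glm(y, X)
    for t in [c for c in TERRITORY_SIZE_TERMS if c not in fit.terms]:
        fit.extra.setdefault("constant_terms", []).append(t)
    return fit


def fit_group_glm(rows, min_rows: int = 10) -> ModelFit:
    """Adult count ~ heterogeneity + richness + male:female ratio +
    dispersion + territory size, Gamma GLM with log link."""
    df = _as_frame(rows)
    X = _drop_constant_predictors(_design(df, GROUP_SIZE_TERMS))
    y = df["n_adults"].to_numpy(float)
    if int(np.sum(np.isfinite(y) & (y > 0))) < min_rows:
        raise ValueError(f"need >= {min_rows} complete rows")
    return fit_gamma_glm(y, X)


def fit_null_glm(rows, response: str) -> ModelFit:
    """Intercept-only Gamma GLM counterpart for LR testing."""
    df = _as_frame(rows)
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    return fit_gamma_glm(df[response].to_numpy(float), X)


def lr_test(full: Union[ModelFit, MixedFit], null: Union[ModelFit, MixedFit]) -> LRTResult:
    """Likelihood-ratio test of a full model against a nested null.

    For GLMs the statistic is the deviance drop (null deviance minus
    residual deviance of the full model when the null is intercept-only,
    else the difference of residual deviances); for mixed fits it is twice
    the log-likelihood difference.  The reference distribution is chi-square
    with df equal to the parameter-count difference.
    """
    if isinstance(full, ModelFit) and isinstance(null, ModelFit):
        if full.n_used != null.n_used:
            raise ValueError("models fitted to different row sets")
        df = len(full.terms) - len(null.terms)
        if df < 0:
            raise ValueError("null model has more parameters than the full model")
        stat = max(0.0, null.deviance - full.deviance)
        # the raw deviance drop is reported; the chi-square reference applies
        # to the dispersion-scaled drop (the anova.glm convention for Gamma)
        p = float(stats.chi2.sf(stat / full.dispersion, df)) if df > 0 else 1.0
        return LRTResult(stat, df, p, full.aic, null.aic)
    if isinstance(full, MixedFit) and isinstance(null, MixedFit):
        if full.n_used != null.n_used:
            raise ValueError("models fitted to different row sets")
        df = (len(full.terms) + len(full.disp_terms)) - (len(null.terms) + len(null.disp_terms))
        if df < 0:
            raise ValueError("null model has more parameters than the full model")
        return LRTResult.from_loglik(
            full.loglik, null.loglik, df, full.aic, null.aic, full.bic, null.bic,
        )
    raise TypeError("full and null must both be ModelFit or both MixedFit")


def _season_design(df: pd.DataFrame, reference: str = "mating") -> pd.DataFrame:
    others = [s for s in SEASONS if s != reference]
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for s in others:
        X[f"season[{s}]"] = (df["season"].astype(str) == s).astype(float)
    return X


def fit_seasonal_glmm(
    rows,
    response: str = "territory_area",
    reference: str = "mating",
    disp_by_season: bool = False,
    se: bool = True,
) -> MixedFit:
    """Season effect on a positive response, group as random intercept.

    Gamma log-link GLMM fitted by Laplace ML.  A near-singular random
    effect (SD < 1e-4) triggers a refit as the fixed-effects-only Gamma
    GLM, returned as a flagged :class:`MixedFit`.
    """
    df = _as_frame(rows)
    if reference not in SEASONS:
        raise ValueError(f"reference must be one of {SEASONS}")
    X = _season_design(df, reference)
    Z = _season_design(df, reference) if disp_by_season else None
    y = df[response].to_numpy(float)
    fit = fit_gamma_glmm(y, X, df["group_id"].to_numpy(), Z=Z, se=se)
    if fit.singular:
        logger.warning(
            "seasonal GLMM on %s: random intercept singular (SD=%.2e); "
            "refitting fixed-effects-only model", response, fit.sd_group,
        )
        fit = _fixed_only_fallback(y, X, Z, df, se=se)
    return fit


def _fixed_only_fallback(y, X, Z, df, se: bool = True) -> MixedFit:
    """Gamma model without the random intercept, in MixedFit form."""
    fit = fit_gamma_glmm(
        y, X, np.zeros(len(y), dtype=int), Z=Z, se=se, force_sigma_zero=True,
    )
    fit.singular = True
    fit.fallback_fixed_only = True
    return fit


def fit_dispersion_model(
    rows,
    response: str = "heterogeneity",
    reference: str = "mating",
    se: bool = True,
) -> tuple[MixedFit, MixedFit, LRTResult]:
    """Constant- vs season-specific-dispersion Gamma GLMM comparison.

    Both models share the mean structure (season fixed effect, group random
    intercept); the seasonal model adds a log-linear dispersion submodel
    with the season factor (2 extra parameters).  Returns
    (constant fit, seasonal fit, 2-df LRT).
    """
    constant = fit_seasonal_glmm(rows, response, reference, disp_by_season=False, se=se)
    seasonal = fit_seasonal_glmm(rows, response, reference, disp_by_season=True, se=se)
    test = LRTResult.from_loglik(
        seasonal.loglik, constant.loglik, 2,
        seasonal.aic, constant.aic, seasonal.bic, constant.bic,
    )
    return constant, seasonal, test


def fit_logdistance_lm(rows, response: str = "dispersion", reference: str = "mating") -> ModelFit:
    """OLS of log(mean inter-patch distance) on season.

    The fallback used when random-intercept variants are near-singular.
    Reports the overall F(2, n-3) and R-squared in ``extra``.
    """
    df = _as_frame(rows)
    y = df[response].to_numpy(float)
    keep = np.isfinite(y) & (y > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("log-distance LM: dropping %d rows (missing or non-positive)", n_dropped)
    df = df.loc[keep]
    X = _season_design(df, reference)
    res = sm.OLS(np.log(df[response].to_numpy(float)), np.asarray(X)).fit()
    fit = ModelFit(
        terms=list(X.columns),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        cov_params=np.asarray(res.cov_params()),
        df_resid=int(res.df_resid),
        loglik=float(res.llf),
        deviance=float(res.ssr),
        null_deviance=float(res.centered_tss),
        aic=float(res.aic),
        dispersion=float(res.mse_resid),
        n_used=int(res.nobs),
        n_dropped=n_dropped,
        family="lognormal-ols",
    )
    fit.extra["f_statistic"] = float(res.fvalue)
    fit.extra["f_df"] = (int(res.df_model), int(res.df_resid))
    fit.extra["f_pvalue"] = float(res.f_pvalue)
    fit.extra["r_squared"] = float(res.rsquared)
    return fit
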