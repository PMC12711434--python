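"""Fitted-model containers shared by the census and territory analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ModelFit", "LRTResult"]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ModelFit:
    """Coefficients and inference summaries for a fixed-effects model fit.

    For Gamma log-link GLMs, Wald statistics are t ratios using the
    Pearson-dispersion-adjusted covariance (the convention of R's
    ``summary.glm``), and rate ratios are the exponentiated coefficients
    with 95% Wald intervals on the log scale.
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    df_resid: int
    loglik: float
    deviance: float
    null_deviance: float
    aic: float
    dispersion: float  # Gamma dispersion (Pearson chi2 / df_resid); 1.0 for OLS sigma^2-free use
    n_used: int
    n_dropped: int = 0
    family: str = "gamma-log"
    extra: dict = field(default_factory=dict)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    @property
    def rate_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def rr_conf_int(self) -> np.ndarray:
        """95% Wald CI for the rate ratios, shape (k, 2)."""
        lo = np.exp(self.params - _Z975 * self.bse)
        hi = np.exp(self.params + _Z975 * self.bse)
        return np.column_stack([lo, hi])

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def table(self) -> pd.DataFrame:
        """Summary table: estimate, SE, t, p, rate ratio, 95% RR CI."""
        ci = self.rr_conf_int
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                "t_value": self.tvalues,
                "p": self.pvalues,
                "rate_ratio": self.rate_ratios,
                "rr_ci_low": ci[:, 0],
                "rr_ci_high": ci[:, 1],
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "estimate": self.params.tolist(),
            "se": self.bse.tolist(),
            "t_value": self.tvalues.tolist(),
            "p": self.pvalues.tolist(),
            "rate_ratio": self.rate_ratios.tolist(),
            "rr_ci_low": self.rr_conf_int[:, 0].tolist(),
            "rr_ci_high": self.rr_conf_int[:, 1].tolist(),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "loglik": self.loglik,
            "aic": self.aic,
            "dispersion": self.dispersion,
            "df_resid": self.df_resid,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "family": self.family,
        }


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of a full model against a nested null."""

    statistic: float  # deviance difference (GLM) or 2*delta-loglik (GLMM)
    df: int
    pvalue: float
    aic_full: float
    aic_null: float
    bic_full: Optional[float] = None
    bic_null: Optional[float] = None

    @classmethod
    def from_loglik(cls, ll_full: float, ll_null: float, df: int,
                    aic_full: float, aic_null: float,
                    bic_full: Optional[float] = None,
                    bic_null: Optional[float] = None) -> "LRTResult":
        stat = max(0.0, 2.0 * (ll_full - ll_null))
        p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
        return cls(stat, df, p, aic_full, aic_null, bic_full, bic_null)
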