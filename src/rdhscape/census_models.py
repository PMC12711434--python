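"""Census-scale statistics: settlement contrasts, the interaction Gamma GLM,
and the sensitivity (power) analysis.

The central model is a Gamma GLM with log link,

    dogs ha^-1 ~ resource ha^-1 x settlement type,

with rural as the reference level, so the resource coefficient is the rural
slope and the interaction measures how the slope changes in urban sites.  The
urban ("combined") slope is the sum of the two, with a delta-method SE.

The sensitivity analysis expresses the detectable urban-rural contrast for
the realized sample sizes as a standardized difference d (noncentral-t power
of the two-sided two-sample t test), and maps it onto rank-test effect sizes
through the normal-shift equivalence AUC = Phi(d/sqrt(2)), delta = 2*AUC - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .fits import ModelFit
from .scoring import CensusSite, dog_density, resource_density

__all__ = [
    "RankTestResult",
    "PowerSpec",
    "rank_sum_test",
    "fit_census_glm",
    "fit_gamma_glm",
    "combined_slope",
    "two_sample_power",
    "d_for_power",
    "d_to_auc",
    "auc_to_cliffs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum result.

    ``u`` is the Mann-Whitney U for the first sample; ``w`` is the
    first-sample rank sum (the R ``wilcox.test`` W equals U).
    """

    u: float
    w: float
    pvalue: float
    continuity: bool
    exact: bool


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample, two-sided power problem: sizes, alpha, Cohen's d."""

    n1: int
    n2: int
    alpha: float = 0.05
    d: float = 0.6

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.d < 0:
            raise ValueError("d must be >= 0")


def rank_sum_test(x: Sequence[float], y: Sequence[float], continuity: bool = True) -> RankTestResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null distribution when min(n1, n2) <= 8 and there are no ties;
    otherwise the normal approximation with tie-corrected variance and
    (optionally) a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method,
        use_continuity=(continuity and not exact),
    )
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0  # rank sum of the first sample
    return RankTestResult(
        u=u, w=w, pvalue=float(res.pvalue),
        continuity=(continuity and not exact), exact=exact,
    )


def fit_gamma_glm(
    y: np.ndarray,
    X: pd.DataFrame,
    drop_nonpositive: bool = True,
    zero_offset: float = 0.0,
) -> ModelFit:
    """Gamma log-link GLM of a positive response on a named design matrix.

    Rows with a non-positive response (outside Gamma support) are dropped
    with a logged count unless ``zero_offset`` adds a constant instead.
    Wald t statistics use the Pearson-dispersion-adjusted covariance.
    """
    y = np.asarray(y, dtype=float)
    X = X.copy()
    if zero_offset:
        y = y + zero_offset
    keep = y > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        if not drop_nonpositive:
            raise ValueError(f"{n_dropped} non-positive response rows (Gamma support)")
        logger.warning("dropping %d non-positive response rows (Gamma support)", n_dropped)
        y, X = y[keep], X.loc[keep]
    finite = np.isfinite(y) & np.isfinite(np.asarray(X, dtype=float)).all(axis=1)
    n_nan = int((~finite).sum())
    if n_nan:
        logger.warning("dropping %d rows with missing predictor/response values", n_nan)
        y, X = y[finite], X.loc[finite]
        n_dropped += n_nan
    n = len(y)
    if n <= X.shape[1]:
        raise ValueError(f"too few rows ({n}) for {X.shape[1]} parameters")
    Xa = np.asarray(X, dtype=float)
    if np.linalg.cond(Xa.T @ Xa) > 1e8 and Xa.shape[1] > 1:
        raise ValueError("singular or near-singular design (condition number > 1e8)")

    model = sm.GLM(y, Xa, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(scale="X2")

    return ModelFit(
        terms=list(X.columns),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        cov_params=np.asarray(res.cov_params(), dtype=float),
        df_resid=int(res.df_resid),
        loglik=float(res.llf),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        # count the Gamma shape parameter alongside the coefficients
        aic=float(-2.0 * res.llf + 2.0 * (X.shape[1] + 1)),
        dispersion=float(res.scale),
        n_used=n,
        n_dropped=n_dropped,
        family="gamma-log",
    )


def census_frame(sites: Sequence[CensusSite]) -> pd.DataFrame:
    """Per-site analysis table: densities, settlement indicator, area."""
    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.id,
                "settlement": s.settlement,
                "area_ha": s.area_ha,
                "dog_density": dog_density(s),
                "dog_density_male": dog_density(s, "M"),
                "dog_density_female": dog_density(s, "F"),
                "resource_density": resource_density(s),
            }
        )
    return pd.DataFrame(rows)


def fit_census_glm(
    sites: Sequence[CensusSite],
    drop_zero_density: bool = True,
    zero_offset: float = 0.0,
) -> ModelFit:
    """The interaction model: dog density ~ resource density x settlement.

    Reference level is rural; terms are the intercept, the rural resource
    slope, the urban main effect, and the resource x urban interaction.
    Sites with zero observed dogs violate Gamma support and are dropped with
    a logged count (set ``zero_offset`` to add a small constant instead).
    """
    df = census_frame(sites)
    for settlement in ("rural", "urban"):
        sub = df[(df.settlement == settlement) & (df.dog_density > 0)]
        if len(sub) < 2:
            raise ValueError(f"need >=2 {settlement} sites with positive dog density")
    urban = (df["settlement"] == "urban").astype(float)
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "resource_density": df["resource_density"],
            "urban": urban,
            "resource_density:urban": df["resource_density"] * urban,
        }
    )
    return fit_gamma_glm(
        df["dog_density"].to_numpy(), X,
        drop_nonpositive=drop_zero_density, zero_offset=zero_offset,
    )


def combined_slope(fit: ModelFit, level: str = "urban") -> tuple[float, float]:
    """Resource slope for a settlement level, with delta-method SE.

    Rural is the reference, so its slope is the ``resource_density``
    coefficient itself; the urban slope adds the interaction, with
    SE = (var1 + var3 + 2 cov13)^(1/2).
    """
    i = fit.terms.index("resource_density")
    if level == "rural":
        return fit.params[i], fit.bse[i]
    if level != "urban":
        raise ValueError(f"level must be 'rural' or 'urban', got {level!r}")
    j = fit.terms.index("resource_density:urban")
    slope = float(fit.params[i] + fit.params[j])
    var = fit.cov_params[i, i] + fit.cov_params[j, j] + 2.0 * fit.cov_params[i, j]
    return slope, float(np.sqrt(var))


def two_sample_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t test at standardized difference d.

    Noncentral-t formulation: df = n1 + n2 - 2, noncentrality
    ncp = d / sqrt(1/n1 + 1/n2).
    """
    df = spec.n1 + spec.n2 - 2
    ncp = spec.d / np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral t loses precision at extreme noncentrality; the
    # missing tail is then numerically 1 (upper) or 0 (lower)
    if not np.isfinite(upper):
        upper = 1.0 if ncp > tcrit else 0.0
    if not np.isfinite(lower):
        lower = 0.0 if ncp > -tcrit else 1.0
    return float(min(1.0, upper + lower))


def d_for_power(target_power: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """The standardized difference d at which the t test reaches target power."""
    if not alpha < target_power < 1.0:
        raise ValueError("target power must lie in (alpha, 1)")

    def gap(d: float) -> float:
        return two_sample_power(PowerSpec(n1, n2, alpha, d)) - target_power

    return float(optimize.brentq(gap, 1e-12, 10.0, xtol=1e-10))


def d_to_auc(d: float) -> float:
    """Mann-Whitney AUC equivalent of Cohen's d under a normal shift."""
    return float(stats.norm.cdf(d / np.sqrt(2.0)))


def auc_to_cliffs(auc: float) -> float:
    """Cliff's delta from the AUC (common-language effect size)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must be in [0, 1]")
    return 2.0 * auc - 1.0
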