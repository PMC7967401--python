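"""Secular-trend inference for monthly search-interest series.

Two complementary analyses per topic:

* the Seasonal Mann-Kendall test — a rank-based trend test that computes
  the Mann-Kendall S statistic separately within each calendar month
  (season) and sums across months, removing seasonal confounding.  The
  variance uses the standard tie correction per season; the normal
  approximation uses the +/-1 continuity correction.  Seasons are treated
  as independent (no serial-correlation correction).
* an ordinary-least-squares slope of RSV on time in fractional years,
  quantifying the trend magnitude in RSV per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gt_io import TopicSeries


@dataclass(frozen=True)
class TrendResult:
    S: int
    var_S: float
    Z: float
    tau: float
    p_two_sided: float
    slope: float
    slope_p: float
    n_years: int
    period: int = 12
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_two_sided)


def significance_stars(p: float) -> str:
    """Conventional significance markers; the study's tables print ***."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _season_s_and_var(x: np.ndarray) -> tuple[int, float]:
    """Mann-Kendall S and tie-corrected variance for one season's values."""
    n = len(x)
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var)


def seasonal_mann_kendall_arrays(
    values: np.ndarray, period: int = 12
) -> tuple[int, float, float, float, float, bool]:
    """Core statistic on a plain array; see :func:`seasonal_mann_kendall`."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n % period != 0:
        raise ValueError(f"series length {n} is not a multiple of period {period}")
    n_cycles = n // period
    if n_cycles < 2:
        raise ValueError("need at least 2 full cycles to form within-season pairs")

    S = 0
    var_S = 0.0
    pairs = 0
    by_season = values.reshape(n_cycles, period)
    for g in range(period):
        s_g, var_g = _season_s_and_var(by_season[:, g])
        S += s_g
        var_S += var_g
        pairs += n_cycles * (n_cycles - 1) // 2

    degenerate = var_S == 0.0
    if degenerate or S == 0:
        Z = 0.0
    elif S > 0:
        Z = (S - 1) / np.sqrt(var_S)
    else:
        Z = (S + 1) / np.sqrt(var_S)
    p = 1.0 if degenerate else float(2.0 * stats.norm.sf(abs(Z)))
    tau = S / pairs
    return S, var_S, float(Z), float(tau), p, degenerate


def seasonal_mann_kendall(
    s: TopicSeries, period: int = 12, alpha: float = 0.05
) -> TrendResult:
    """Seasonal Mann-Kendall test plus OLS slope for an imputed series.

    Requires a whole number (>= 3) of cycles.  A fully tied series
    (variance zero) yields Z = 0, p = 1 and the degenerate flag.
    """
    if not s.imputed:
        raise ValueError("seasonal_mann_kendall requires an imputed series")
    if len(s) < 3 * period:
        raise ValueError("need at least 3 full cycles")
    S, var_S, Z, tau, p, degenerate = seasonal_mann_kendall_arrays(s.values, period)
    slope, _, slope_p = ols_slope(s)
    return TrendResult(
        S=S,
        var_S=var_S,
        Z=Z,
        tau=tau,
        p_two_sided=p,
        slope=slope,
        slope_p=slope_p,
        n_years=len(s) // period,
        period=period,
        degenerate=degenerate,
    )


def ols_slope_arrays(values: np.ndarray, period: int = 12) -> tuple[float, float, float]:
    """Closed-form OLS of value on time in fractional years.

    Returns (slope per year, intercept, two-sided slope p from the t
    distribution with n-2 degrees of freedom).
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points for a regression slope")
    t = np.arange(n) / period
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ yc) / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = yc - slope * tc
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(slope / se), dof))
    return slope, intercept, p


def ols_slope(s: TopicSeries, period: int = 12) -> tuple[float, float, float]:
    """OLS slope in RSV/year for an imputed monthly series (>= 24 months)."""
    if not s.imputed:
        raise ValueError("ols_slope requires an imputed series")
    if len(s) < 24:
        raise ValueError("need at least 24 months for a yearly slope")
    return ols_slope_arrays(s.values, period)
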