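"""Seasonal structure of monthly search-interest series.

An additive trend + seasonal + remainder decomposition in the STL family,
built on a local polynomial (Loess) smoother with tricube weights and a
*periodic* seasonal component: one fixed value per calendar month
(the cycle-subseries mean), matching how the study reports a single
seasonal component per month.  Seasonality presence is declared by a
harmonic-regression F-test: the monthly series is regressed on a linear
time term with and without the first two Fourier harmonics of the annual
cycle, and the nested-model F statistic decides whether the harmonics
explain significant variance.

Summaries per series: the calendar months of the highest and lowest
seasonal component and the yearly amplitude (max minus min of the twelve
monthly components, in RSV units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gt_io import TopicSeries

MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


@dataclass
class SeasonalDecomposition:
    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    monthly_component: np.ndarray  # 12 values, January..December, sum 0
    peak_month: str
    trough_month: str
    amplitude: float
    seasonal_present: bool | None = None
    seasonal_p: float | None = None
    flags: list[str] = field(default_factory=list)


def loess_smooth(
    xs: np.ndarray, ys: np.ndarray, span: float = 0.5, degree: int = 1
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    At each ``x`` the ``q = max(degree + 1, ceil(span * n))`` nearest
    points are fit by weighted least squares (degree 0 or 1) with weights
    ``(1 - (d / d_max)^3)^3`` and the local fit is evaluated at ``x``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs)
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    q = min(n, max(degree + 1, int(np.ceil(span * n))))

    fitted = np.empty(n)
    for i, x0 in enumerate(xs):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dq = d[idx]
        dmax = dq.max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = np.clip(1.0 - (dq / dmax) ** 3, 0.0, None) ** 3
        # the farthest neighbour gets weight 0; keep a floor so the
        # local system stays solvable when q is tiny
        if w.sum() == 0:
            w = np.ones(q)
        xw = xs[idx]
        yw = ys[idx]
        if degree == 0:
            fitted[i] = float(np.average(yw, weights=w))
        else:
            sw = w.sum()
            xbar = float((w * xw).sum() / sw)
            ybar = float((w * yw).sum() / sw)
            sxx = float((w * (xw - xbar) ** 2).sum())
            if sxx == 0:
                fitted[i] = ybar
            else:
                beta = float((w * (xw - xbar) * (yw - ybar)).sum() / sxx)
                fitted[i] = ybar + beta * (x0 - xbar)
    return fitted


def default_trend_span(n: int, period: int = 12) -> float:
    """Trend window as a fraction of the series; wide enough to bridge a cycle."""
    return max(0.2, 1.5 * period / n)


def _monthly_means(values: np.ndarray, month_of: np.ndarray) -> np.ndarray:
    comp = np.empty(12)
    for m in range(12):
        comp[m] = values[month_of == m].mean()
    return comp - comp.mean()


def stl_periodic(
    s: TopicSeries,
    period: int = 12,
    n_iterations: int = 2,
    trend_span: float | None = None,
    run_test: bool = True,
    alpha: float = 0.05,
) -> SeasonalDecomposition:
    """Additive decomposition with a periodic (per-calendar-month) seasonal.

    Iterates between Loess trend estimation and cycle-subseries means:
    the trend is first fit to the raw series, the detrended values are
    averaged per calendar month and centred to give the seasonal
    component, and the trend is re-fit to the deseasonalised series.
    The remainder is defined as input - trend - seasonal, so the additive
    identity is exact.
    """
    if not s.imputed:
        raise ValueError("stl_periodic requires an imputed series")
    y = np.asarray(s.values, dtype=float)
    n = len(y)
    if n % period != 0:
        raise ValueError(f"length {n} is not a whole number of {period}-month cycles")
    if n < 3 * period:
        raise ValueError("need at least 3 full cycles")
    if trend_span is None:
        trend_span = default_trend_span(n, period)

    t = np.arange(n, dtype=float)
    month_of = np.asarray(s.months.month) - 1  # 0 = January
    trend = loess_smooth(t, y, span=trend_span, degree=1)
    comp = np.zeros(12)
    for _ in range(n_iterations):
        comp = _monthly_means(y - trend, month_of)
        seasonal = comp[month_of]
        trend = loess_smooth(t, y - seasonal, span=trend_span, degree=1)
    seasonal = comp[month_of]
    remainder = y - trend - seasonal

    peak_idx = int(np.argmax(comp))
    trough_idx = int(np.argmin(comp))
    flags = []
    if np.count_nonzero(comp == comp[peak_idx]) > 1 or np.count_nonzero(
        comp == comp[trough_idx]
    ) > 1:
        flags.append("tie")
    if np.allclose(comp, 0.0):
        flags.append("degenerate")
    d = SeasonalDecomposition(
        trend=trend,
        seasonal=seasonal,
        remainder=remainder,
        monthly_component=comp,
        peak_month=MONTH_NAMES[peak_idx],
        trough_month=MONTH_NAMES[trough_idx],
        amplitude=float(comp.max() - comp.min()),
        flags=flags,
    )
    if run_test:
        d.seasonal_present, d.seasonal_p = seasonality_test(s, period=period, alpha=alpha)
    return d


def seasonality_test(
    s: TopicSeries, period: int = 12, alpha: float = 0.05
) -> tuple[bool, float]:
    """Harmonic-regression F-test for the presence of an annual cycle.

    Compares nested OLS fits of the series on (a) intercept + linear time
    versus (b) the same plus sine/cosine terms at 1 and 2 cycles per
    year.  Returns (seasonal_present, p).
    """
    if not s.imputed:
        raise ValueError("seasonality_test requires an imputed series")
    y = np.asarray(s.values, dtype=float)
    n = len(y)
    if n % period != 0 or n < 3 * period:
        raise ValueError("need a whole number (>= 3) of cycles")
    t = np.arange(n, dtype=float)
    w = 2.0 * np.pi * t / period
    X0 = np.column_stack([np.ones(n), t])
    X1 = np.column_stack(
        [np.ones(n), t, np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)]
    )
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    df_extra = X1.shape[1] - X0.shape[1]
    df_resid = n - X1.shape[1]
    if rss1 <= 0:
        return True, 0.0
    f = ((rss0 - rss1) / df_extra) / (rss1 / df_resid)
    p = float(stats.f.sf(f, df_extra, df_resid))
    return p < alpha, p


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def seasonal_summary(d: SeasonalDecomposition) -> tuple[str, str, float]:
    """(peak month, trough month, amplitude) from the monthly components.

    Amplitude is max minus min of the twelve components; month ties break
    toward the earliest calendar month and carry the "tie" flag on the
    decomposition.
    """
    comp = np.asarray(d.monthly_component, dtype=float)
    peak = MONTH_NAMES[int(np.argmax(comp))]
    trough = MONTH_NAMES[int(np.argmin(comp))]
    return peak, trough, float(comp.max() - comp.min())
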