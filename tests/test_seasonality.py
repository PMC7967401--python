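import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from dermtrends.seasonality import (
    MONTH_NAMES,
    SeasonalDecomposition,
    loess_smooth,
    seasonal_summary,
    seasonality_test,
    stl_periodic,
)


def test_loess_reproduces_lines():
    xs = np.arange(20.0)
    ys = 3.0 * xs - 7.0
    for span in (0.3, 0.7, 1.0):
        assert loess_smooth(xs, ys, span=span, degree=1) == pytest.approx(ys, abs=1e-9)


def test_loess_degree0_reproduces_constants():
    xs = np.arange(15.0)
    assert loess_smooth(xs, np.full(15, 4.2), span=0.5, degree=0) == pytest.approx(
        np.full(15, 4.2)
    )


def test_loess_matches_direct_wls_at_middle_point():
    # 7-point toy series, q = ceil(5/7 * 7) = 5 nearest neighbours
    xs = np.arange(7.0)
    ys = np.array([2.0, 4.0, 3.0, 8.0, 6.0, 5.0, 9.0])
    fitted = loess_smooth(xs, ys, span=5 / 7, degree=1)

    x0 = 3.0
    d = np.abs(xs - x0)
    idx = np.argsort(d)[:5]
    w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
    X = np.column_stack([np.ones(5), xs[idx]])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys[idx])
    assert fitted[3] == pytest.approx(beta[0] + beta[1] * x0, abs=1e-10)


def test_loess_contract_errors():
    with pytest.raises(ValueError, match="increasing"):
        loess_smooth([0.0, 0.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        loess_smooth([0.0], [1.0], degree=1)


def test_stl_recovers_exact_additive_structure():
    # geometric convergence: run the trend/seasonal loop to convergence
    t = np.arange(144, dtype=float)
    seasonal = 10.0 * np.cos(2 * np.pi * t / 12)
    y = 30 + 0.5 * t + seasonal
    d = stl_periodic(make_series(y), run_test=False, n_iterations=10)
    assert d.monthly_component == pytest.approx(seasonal[:12], abs=1e-6)
    assert np.max(np.abs(d.remainder)) < 1e-6
    assert d.peak_month == "January"
    # at the default two iterations the leakage is still visible but small
    d2 = stl_periodic(make_series(y), run_test=False)
    assert d2.monthly_component == pytest.approx(seasonal[:12], abs=0.1)


def test_stl_constant_input():
    d = stl_periodic(make_series(np.full(36, 12.0)), run_test=False)
    assert d.monthly_component == pytest.approx(np.zeros(12), abs=1e-9)
    assert d.trend == pytest.approx(np.full(36, 12.0), abs=1e-9)
    assert "degenerate" in d.flags


def test_stl_requires_whole_cycles():
    with pytest.raises(ValueError, match="cycles"):
        stl_periodic(make_series(np.arange(40, dtype=float)))


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=40)
def test_decomposition_identities(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.choice([36, 96, 192]))
    y = np.clip(rng.normal(40, 10, n) + rng.uniform(0, 3) * np.arange(n) / 12, 0.1, None)
    d = stl_periodic(make_series(y), run_test=False)
    assert d.trend + d.seasonal + d.remainder == pytest.approx(y, abs=1e-9)
    assert abs(d.monthly_component.sum()) < 1e-9
    assert d.amplitude >= 0
    assert d.peak_month == MONTH_NAMES[int(np.argmax(d.monthly_component))]
    assert d.trough_month == MONTH_NAMES[int(np.argmin(d.monthly_component))]


def test_amplitude_invariant_to_added_linear_trend():
    rng = np.random.default_rng(8)
    base = 40 + 12 * np.cos(2 * np.pi * np.arange(192) / 12) + rng.normal(0, 1, 192)
    d0 = stl_periodic(make_series(base), run_test=False)
    d1 = stl_periodic(make_series(base + 5.0 * np.arange(192) / 12 + 30), run_test=False)
    assert abs(d0.amplitude - d1.amplitude) <= 0.5


def test_agreement_with_statsmodels_stl():
    STL = pytest.importorskip("statsmodels.tsa.seasonal").STL
    import pandas as pd

    rng = np.random.default_rng(13)
    t = np.arange(192, dtype=float)
    y = 50 + 3 * t / 12 + 8 * np.cos(2 * np.pi * (t - 6) / 12) + rng.normal(0, 2, 192)
    s = make_series(y)
    d = stl_periodic(s, run_test=False)
    res = STL(pd.Series(y, index=s.months.to_timestamp()), period=12, robust=False).fit()
    month_of = np.asarray(s.months.month) - 1
    sm_comp = np.array([res.seasonal.values[month_of == m].mean() for m in range(12)])
    sm_comp -= sm_comp.mean()
    assert np.max(np.abs(d.monthly_component - sm_comp)) < 0.5


def test_seasonality_test_detects_pure_harmonic():
    t = np.arange(96, dtype=float)
    y = 20 + 0.3 * t + 5 * np.sin(2 * np.pi * t / 12)
    present, p = seasonality_test(make_series(y))
    assert present and p < 1e-6


def test_seasonality_test_null_calibration():
    # a trend with iid noise should rarely be declared seasonal
    rng = np.random.default_rng(314)
    t = np.arange(192, dtype=float)
    false_positives = sum(
        seasonality_test(make_series(10 + 0.5 * t / 12 + rng.normal(0, 0.5, 192)))[0]
        for _ in range(1000)
    )
    assert false_positives <= 70  # nominal 5% level, >= 93% non-rejection


def test_aseasonal_fixture_topic_is_not_flagged():
    # a trending but aseasonal series, like the hair-loss topic
    rng = np.random.default_rng(21)
    y = 20 + 1.34 * np.arange(192) / 12 + rng.normal(0, 2, 192)
    present, _ = seasonality_test(make_series(y))
    assert not present


@pytest.mark.parametrize(
    "peak,peak_m,trough,trough_m,amplitude",
    [
        (21.61, "May", -22.16, "December", 43.77),
        (5.32, "July", -3.20, "December", 8.52),
    ],
)
def test_seasonal_summary_amplitude_arithmetic(peak, peak_m, trough, trough_m, amplitude):
    comp = np.zeros(12)
    comp[MONTH_NAMES.index(peak_m)] = peak
    comp[MONTH_NAMES.index(trough_m)] = trough
    d = SeasonalDecomposition(
        trend=np.zeros(12), seasonal=np.zeros(12), remainder=np.zeros(12),
        monthly_component=comp, peak_month=peak_m, trough_month=trough_m,
        amplitude=peak - trough,
    )
    got_peak, got_trough, got_amp = seasonal_summary(d)
    assert (got_peak, got_trough) == (peak_m, trough_m)
    assert got_amp == pytest.approx(amplitude, abs=1e-9)


def test_seasonal_summary_all_zero_components():
    d = SeasonalDecomposition(
        trend=np.zeros(12), seasonal=np.zeros(12), remainder=np.zeros(12),
        monthly_component=np.zeros(12), peak_month="January", trough_month="January",
        amplitude=0.0,
    )
    assert seasonal_summary(d)[2] == 0.0
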