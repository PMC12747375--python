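import math

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.tsa.stattools import adfuller

from evcl.series_io import AnnualSeries, rescale
from evcl.stationarity import (UnitRootSpec, ZA_CRITICAL_VALUES, adf_lag_search,
                               adf_test, za_test)
from evcl.synthetic_data import SimConfig, gen_urbanization

FIXED0 = UnitRootSpec(trend="c", max_lag=0, criterion="fixed", fixed_lag=0)


class TestADF:
    def test_published_gdp_row(self, gdp_pct):
        """Intercept-only Dickey-Fuller on the 44-year GDP growth series:
        alpha1 = 6.346, gamma = -0.521, tau = -3.690, rejecting at 1%."""
        r = adf_test(gdp_pct, FIXED0)
        assert round(r.intercept, 3) == 6.346
        assert round(r.gamma, 3) == -0.521
        assert r.tau == pytest.approx(-3.690, abs=0.005)
        assert r.criticals["1%"] == pytest.approx(-3.592, abs=1e-3)
        assert r.criticals["5%"] == pytest.approx(-2.931, abs=1e-3)
        assert r.criticals["10%"] == pytest.approx(-2.604, abs=1e-3)
        assert r.reject_at == "1%" and r.lags_used == 0

    def test_matches_statsmodels_adfuller(self, gdp_pct):
        stat, pval, _, _, crits, _ = adfuller(gdp_pct.values, maxlag=4,
                                              regression="c", autolag="AIC")
        r = adf_test(gdp_pct, UnitRootSpec(trend="c", max_lag=4, criterion="aic"))
        assert r.tau == pytest.approx(stat, abs=1e-8)
        assert r.p_value == pytest.approx(pval, abs=1e-8)
        for lvl in ("1%", "5%", "10%"):
            assert r.criticals[lvl] == pytest.approx(crits[lvl], abs=1e-8)

    def test_scale_invariance_of_tau(self, gdp_pct):
        r1 = adf_test(gdp_pct, FIXED0)
        r2 = adf_test(rescale(gdp_pct, "fraction"), FIXED0)
        assert r2.tau == pytest.approx(r1.tau, rel=1e-12)
        assert r2.gamma == pytest.approx(r1.gamma, rel=1e-12)  # dimensionless
        assert r2.intercept == pytest.approx(r1.intercept / 100.0, rel=1e-12)

    def test_three_point_hand_ols(self):
        """y = {1,2,4}: dy = {1,2} regressed on (1, y_lag) solves exactly
        dy = 0 + 1*... by the 2x2 normal equations [[2,3],[3,5]] beta = [3,5]."""
        y = np.array([1.0, 2.0, 4.0])
        beta = np.linalg.solve(np.array([[2.0, 3.0], [3.0, 5.0]]),
                               np.array([3.0, 5.0]))
        r = adf_test(y, FIXED0)
        assert r.intercept == pytest.approx(beta[0])
        assert r.gamma == pytest.approx(beta[1])

    def test_fixed_lag_equals_search_path_entry(self, gdp_pct):
        path = adf_lag_search(gdp_pct.values, "c", max_lag=4)
        for crit in ("aic", "bic", "maic"):
            best = min(path, key=lambda row: row[crit])["lag"]
            r = adf_test(gdp_pct, UnitRootSpec(trend="c", max_lag=4, criterion=crit))
            assert r.lags_used == best

    def test_short_and_constant_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            adf_test(np.array([1.0, 2.0]), FIXED0)
        with pytest.raises(ValueError, match="constant"):
            adf_test(np.ones(20), FIXED0)

    def test_size_on_driftless_random_walks(self):
        """Nominal 5% test rejects in about 5% of driftless random walks."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            y = np.cumsum(rng.standard_normal(500))
            r = adf_test(y, FIXED0)
            rejections += r.tau < r.criticals["5%"]
        assert 0.02 <= rejections / 200 <= 0.08


def _za_oracle(y, tb_range, lag):
    """Brute-force trend-break grid with raw numpy lstsq, independent of the
    implementation's design-matrix builder."""
    dy = np.diff(y)
    n = dy.size
    rows = np.arange(lag, n)
    t = rows + 2.0
    best = None
    for tb in tb_range:
        cols = [np.ones(rows.size), np.where(t > tb, t - tb, 0.0), t, y[rows]]
        cols += [dy[rows - i] for i in range(1, lag + 1)]
        X = np.column_stack(cols)
        beta, rss_arr, *_ = np.linalg.lstsq(X, dy[rows], rcond=None)
        resid = dy[rows] - X @ beta
        rss = float(resid @ resid)
        sigma2 = rss / (rows.size - X.shape[1])
        se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[3, 3])
        tau = beta[3] / se
        if best is None or tau < best[0]:
            best = (tau, tb)
    return best


class TestZA:
    def test_published_urbanization_row(self, urban_pct):
        """Trend-break search on the urbanization series: tau = -4.922,
        significant at 5% but not 1%, with the trend-shift coefficient 0.483
        and time-trend coefficient 0.155 of the published regression."""
        r = za_test(urban_pct, model="trend", max_lag=2, selection="aic")
        assert r.tau == pytest.approx(-4.922, abs=0.005)
        assert round(r.break_trend, 3) == 0.483
        assert round(r.trend_coef, 3) == 0.155
        assert round(r.gamma + 1.0, 3) == 0.505  # levels-form coefficient
        assert r.reject_at == "5%"
        assert r.lags_used == 1

    def test_statistic_matches_grid_oracle(self, rng):
        y = np.cumsum(rng.normal(0.2, 1.0, 20)) + 5.0
        n = y.size
        lo, hi = math.ceil(0.15 * n), math.floor(0.85 * n)
        tau_o, tb_o = _za_oracle(y, range(lo, hi + 1), lag=0)
        r = za_test(y, model="trend", max_lag=0, selection="min_t")
        assert r.tau == pytest.approx(tau_o, abs=1e-10)
        assert r.break_year == tb_o  # plain positional labels for raw arrays

    def test_engineered_break_located(self):
        """Slope break engineered at year 20 of a 40-year near-linear series
        is located within one year."""
        cfg = SimConfig(n_years=40, start_year=1, seed=0, urban_a=0.8,
                        urban_b=1.6, urban_c=0.004, urban_noise_sd=0.005,
                        break_year=20, break_slope=0.03)
        series = rescale(gen_urbanization(cfg), "percent")
        r = za_test(series, model="trend", selection="aic")
        assert abs(r.break_year - 20) <= 1

    def test_break_coefficients_exposed_per_model(self, urban_pct):
        r_b = za_test(urban_pct, model="both", max_lag=0)
        assert r_b.break_intercept is not None and r_b.break_trend is not None
        r_i = za_test(urban_pct, model="intercept", max_lag=0)
        assert r_i.break_intercept is not None and r_i.break_trend is None

    def test_critical_values_per_model(self):
        assert ZA_CRITICAL_VALUES["trend"] == (-4.93, -4.42, -4.11)
        assert ZA_CRITICAL_VALUES["both"][1] == -5.08

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            za_test(np.arange(10.0), model="trend")
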