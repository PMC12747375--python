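import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evcl.growth_models import (DMResult, GompertzParams, PearlParams,
                                assemble_gompertz, build_proxy, compare_models,
                                diagnostics, dm_test, fit_loglinear,
                                gompertz_eval, gompertz_inflection, pearl_eval,
                                pearl_fit)
from evcl.series_io import AnnualSeries
from evcl.synthetic_data import gen_proxy_pair

EQ_PARAMS = GompertzParams(a=28.64, b=0.123, c=0.045)  # the fitted stage curve


class TestCurves:
    def test_gompertz_asymptote_and_origin(self):
        assert gompertz_eval(1e6, EQ_PARAMS) == pytest.approx(28.64)
        assert gompertz_eval(0.0, EQ_PARAMS) == pytest.approx(
            28.64 * math.exp(-0.123))
        assert round(gompertz_eval(0.0, EQ_PARAMS), 4) == 25.3253

    def test_inflection_ordinates(self):
        """Gompertz inflects at a/e (asymmetric), the logistic at a/2."""
        x_infl, y_infl = gompertz_inflection(EQ_PARAMS)
        assert x_infl == pytest.approx(math.log(0.123) / 0.045)
        assert gompertz_eval(x_infl, EQ_PARAMS) == pytest.approx(
            28.64 / math.e, abs=1e-10)
        p = PearlParams(a=2.0, b=5.0, c=0.3)
        assert pearl_eval(math.log(5.0) / 0.3, p) == pytest.approx(1.0, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.1, 100), b=st.floats(0.01, 10), c=st.floats(0.001, 1),
           x=st.floats(0, 10))
    def test_gompertz_increasing_and_bounded(self, a, b, c, x):
        # x range kept where the exponent is numerically resolvable; in exact
        # arithmetic the bounds are open for all x
        p = GompertzParams(a, b, c)
        y0, y1 = gompertz_eval(x, p), gompertz_eval(x + 1.0, p)
        assert 0 < y0 < a and y1 > y0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(a=1.0, b=-0.1, c=0.1)
        with pytest.raises(ValueError):
            assemble_gompertz(fit_loglinear([1, 2, 3], [1.0, 0.5, 0.25]), a=0.0)


class TestProxy:
    def test_corrected_maximum_matches_published(self, gdp_pct):
        """1.1 x 28.64 (2-dp-rounded max) = 31.504; full precision 31.5094."""
        proxy = build_proxy(gdp_pct, headroom=1.1, max_decimals=2)
        assert proxy.x_max_corrected == pytest.approx(31.504)
        exact = build_proxy(gdp_pct, headroom=1.1)
        assert exact.x_max_corrected == pytest.approx(1.1 * 28.64487959)
        assert np.all(proxy.z > 0) and np.all(exact.z > 0)

    def test_toy_values_and_max_year_headroom(self):
        s = AnnualSeries(2000, [10.0, 20.0], "percent")
        proxy = build_proxy(s, headroom=1.1)
        np.testing.assert_allclose(proxy.z, [12.0, 2.0])
        # at the maximizing year z equals (headroom - 1) x max
        assert proxy.z[1] == pytest.approx(0.1 * 20.0)

    def test_headroom_at_most_one_rejected(self):
        s = AnnualSeries(2000, [10.0, 20.0], "percent")
        with pytest.raises(ValueError, match="headroom"):
            build_proxy(s, headroom=1.0)


class TestLoglinearFit:
    def test_exact_recovery(self):
        x = np.arange(1.0, 21.0)
        z = 0.5 * np.exp(-0.08 * x)
        fit = fit_loglinear(x, z)
        assert fit.b == pytest.approx(0.5, rel=1e-12)
        assert fit.c == pytest.approx(0.08, rel=1e-12)
        assert fit.diag_log.r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_three_se(self):
        x = np.linspace(1, 20, 200)
        x, z = gen_proxy_pair(GompertzParams(1.0, 0.5, 0.08), x, 0.05, seed=42)
        fit = fit_loglinear(x, z)
        assert abs(math.log(fit.b) - math.log(0.5)) < 3 * fit.se_log_b
        assert abs(fit.c - 0.08) < 3 * fit.se_c

    def test_r2_equals_squared_correlation(self, rng):
        x = np.arange(30.0)
        z = np.exp(0.5 - 0.03 * x + rng.normal(0, 0.1, 30))
        fit = fit_loglinear(x, z)
        r = np.corrcoef(np.log(z), x)[0, 1]
        assert fit.diag_log.r2 == pytest.approx(r ** 2, rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_loglinear([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            fit_loglinear([1.0, 2.0, 3.0], [1.0, -1.0, 2.0])
        with pytest.raises(ValueError, match="constant regressor"):
            fit_loglinear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_assemble_packages_supplied_asymptote(self):
        x = np.arange(1.0, 21.0)
        fit = fit_loglinear(x, 0.123 * np.exp(-0.045 * x))
        p = assemble_gompertz(fit, a=28.64)
        assert (p.a, round(p.b, 3), round(p.c, 3)) == (28.64, 0.123, 0.045)
        xi, yi = gompertz_inflection(p)
        assert gompertz_eval(xi, p) == pytest.approx(p.a / math.e)


class TestPearlFit:
    def test_exact_recovery_with_known_asymptote(self):
        x = np.linspace(0, 30, 25)
        y = pearl_eval(x, PearlParams(2.0, 8.0, 0.25))
        p, diag = pearl_fit(x, y, a=2.0)
        assert p.b == pytest.approx(8.0, rel=1e-10)
        assert p.c == pytest.approx(0.25, rel=1e-10)
        assert diag.rmse == pytest.approx(0.0, abs=1e-12)

    def test_profiled_asymptote_matches_grid_oracle(self):
        x = np.linspace(0, 9, 10)
        y = pearl_eval(x, PearlParams(1.5, 4.0, 0.5))
        grid = np.linspace(1.1, 3.0, 60) * np.max(y) / np.max(y)  # plain grid
        grid = np.linspace(np.max(y) * 1.01, 3.0, 60)
        # brute-force oracle: RSS of the linearized fit at each grid value
        best_a, best_rss = None, np.inf
        for a in grid:
            w = np.log(a / y - 1.0)
            A = np.column_stack([np.ones_like(x), x])
            beta, *_ = np.linalg.lstsq(A, w, rcond=None)
            pred = a / (1.0 + math.exp(beta[0]) * np.exp(beta[1] * x))
            rss = float(np.sum((y - pred) ** 2))
            if rss < best_rss:
                best_a, best_rss = a, rss
        p, _ = pearl_fit(x, y, grid=grid)
        assert p.a == pytest.approx(best_a)

    def test_y_above_asymptote_rejected(self):
        with pytest.raises(ValueError, match="below"):
            pearl_fit([0.0, 1.0, 2.0], [0.5, 1.0, 2.5], a=2.0)


class TestComparison:
    def test_perfect_fit_diagnostics(self):
        obs = np.array([1.0, 2.0, 3.0])
        d = diagnostics(obs, obs, k=2)
        assert (d.rmse, d.mae, d.max_ae) == (0.0, 0.0, 0.0)
        assert d.r2 == 1.0

    def test_residual_arithmetic(self):
        obs = np.array([1.0, -1.0, 2.0])
        d = diagnostics(obs, np.zeros(3), k=1)
        assert d.rmse == pytest.approx(math.sqrt(2.0))
        assert d.mae == pytest.approx(4.0 / 3.0)
        assert d.max_ae == 2.0
        assert d.aic == pytest.approx(3 * math.log(6.0 / 3.0) + 2)
        assert d.bic == pytest.approx(3 * math.log(2.0) + math.log(3.0))

    def test_scale_consistency(self, rng):
        obs = rng.normal(10, 2, 40)
        pred = obs + rng.normal(0, 1, 40)
        d1 = diagnostics(obs, pred, k=2)
        d2 = diagnostics(obs * 7.0, pred * 7.0, k=2)
        assert d2.r2 == pytest.approx(d1.r2)
        for f in ("rmse", "mae", "max_ae"):
            assert getattr(d2, f) == pytest.approx(7.0 * getattr(d1, f))

    def test_dm_degenerate_flagged(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = obs - 0.1
        _, _, dm = compare_models(obs, pred, pred, 2, 3)
        assert dm.undefined and math.isnan(dm.statistic)

    def test_dm_detects_dominated_model(self, rng):
        obs = rng.normal(0, 1, 200)
        good = obs + rng.normal(0, 0.1, 200)
        bad = obs + rng.normal(0, 1.0, 200)
        d1, d2, dm = compare_models(obs, good, bad, 2, 2)
        assert d1.rmse < d2.rmse
        assert dm.statistic < 0 and dm.p_value < 0.05
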