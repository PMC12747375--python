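"""GM(1,1) gray forecaster for short, positive annual series.

The gray model accumulates the raw series x0 into x1 (running cumulative
sum), forms background values z1(k) = (x1(k) + x1(k-1))/2, and estimates
the development coefficient a and control variable b by least squares from

    x0(k) = b - a * z1(k),    k = 2..n.

The restored (inverse-accumulated) prediction has the closed form

    x0_hat(k) = (x0(1) - b/a) * (1 - e^a) * e^{-a(k-1)},   k >= 2,

so successive predictions share a constant ratio e^{-a}. The same closed
form extends to k <= 0, which is how the bundled run backcasts a held-out
early window for validation after training on the recent sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.stattools import durbin_watson

from .series_io import AnnualSeries

__all__ = [
    "GM11Model",
    "ForecastValidation",
    "fit_gm11",
    "predict_gm11",
    "predict_years",
    "validate_forecast",
]


@dataclass(frozen=True)
class GM11Model:
    a_dev: float      # development coefficient (negative for a growing series)
    b_ctrl: float     # control variable (level term)
    x0_first: float   # first training observation
    start_year: int   # year of x0(1)
    n_train: int      # training length

    @property
    def train_years(self) -> tuple[int, int]:
        return self.start_year, self.start_year + self.n_train - 1


def fit_gm11(x0: AnnualSeries) -> GM11Model:
    """Least-squares GM(1,1) fit; requires length >= 4 and positive data."""
    v = x0.values
    if v.size < 4:
        raise ValueError("GM(1,1) needs at least 4 observations")
    if np.any(v <= 0):
        raise ValueError("GM(1,1) requires strictly positive data")
    x1 = np.cumsum(v)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z1, np.ones(z1.size)])
    coef, *_ = np.linalg.lstsq(B, v[1:], rcond=None)
    a, b = float(coef[0]), float(coef[1])
    return GM11Model(a_dev=a, b_ctrl=b, x0_first=float(v[0]),
                     start_year=x0.start_year, n_train=int(v.size))


def _restored(m: GM11Model, k) -> np.ndarray:
    """Closed-form restored value at (possibly non-positive) index k; k=1 is
    the anchored first observation."""
    k = np.asarray(k, dtype=float)
    if m.a_dev == 0.0:
        raise ZeroDivisionError("degenerate model: development coefficient is 0")
    amp = (m.x0_first - m.b_ctrl / m.a_dev) * (1.0 - math.exp(m.a_dev))
    out = amp * np.exp(-m.a_dev * (k - 1.0))
    return np.where(k == 1.0, m.x0_first, out)


def predict_gm11(m: GM11Model, horizon: int) -> AnnualSeries:
    """Restored predictions for k = 2 .. n_train + horizon (years start+1 on).

    The one-step ratio between successive predictions is constant at
    exp(-a_dev).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    ks = np.arange(2, m.n_train + horizon + 1)
    return AnnualSeries(m.start_year + 1, _restored(m, ks))


def predict_years(m: GM11Model, first: int, last: int) -> AnnualSeries:
    """Restored values for an arbitrary year range, including backcasts
    (years before the training start map to k <= 0)."""
    if first > last:
        raise ValueError("first must be <= last")
    ks = np.arange(first, last + 1) - m.start_year + 1
    return AnnualSeries(first, _restored(m, ks))


@dataclass(frozen=True)
class ForecastValidation:
    mape: float            # percent
    rmse: float
    r2: float
    dw: float              # Durbin-Watson on residuals in year order
    n: int
    mape_defined: bool = True
    dw_defined: bool = True


def validate_forecast(pred: AnnualSeries, obs: AnnualSeries) -> ForecastValidation:
    """Score predictions against observations on their overlapping years.

    A zero observation leaves MAPE undefined (flagged, not raised); an
    all-zero residual vector leaves the Durbin-Watson ratio undefined.
    """
    first = max(pred.start_year, obs.start_year)
    last = min(pred.end_year, obs.end_year)
    if last - first + 1 < 2:
        raise ValueError("need at least 2 overlapping years to validate")
    p = pred.window(first, last).values
    o = obs.window(first, last).values
    resid = o - p
    n = o.size
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    tss = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else (1.0 if rmse == 0 else -math.inf)
    if np.any(o == 0):
        mape, mape_ok = math.nan, False
    else:
        mape, mape_ok = float(np.mean(np.abs(resid / o)) * 100.0), True
    if np.all(resid == 0):
        dw, dw_ok = math.nan, False
    else:
        dw, dw_ok = float(durbin_watson(resid)), True
    return ForecastValidation(mape=mape, rmse=rmse, r2=r2, dw=dw, n=n,
                              mape_defined=mape_ok, dw_defined=dw_ok)
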