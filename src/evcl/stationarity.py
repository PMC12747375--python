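"""Unit-root diagnostics: augmented Dickey-Fuller and Zivot-Andrews tests.

Both tests are run as pre-fit checks on the annual series feeding the stage
model. The ADF regression is

    dy_t = a1 [+ g_t * t] + gamma * y_{t-1} + sum_i beta_i dy_{t-i} + e_t,

with the left-tailed t-ratio of gamma as the test statistic and MacKinnon
finite-sample critical values. The Zivot-Andrews variant augments the
regression with a one-time structural break at an unknown year — an
intercept shift DU_t, a trend-slope shift DT_t, or both — and searches the
trimmed interior of the sample for the break date, either by minimizing the
regression AIC or by the conventional most-negative-t rule.

Coefficient estimation goes through statsmodels OLS so that every reported
statistic carries a textbook standard error; the break-date grid itself is
implemented here (statsmodels' zivot_andrews offers only minimum-t
selection and does not expose the break-dummy coefficients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tsa.adfvalues import mackinnoncrit, mackinnonp

from .series_io import AnnualSeries

__all__ = [
    "UnitRootSpec",
    "UnitRootResult",
    "adf_test",
    "adf_lag_search",
    "za_test",
    "ZA_CRITICAL_VALUES",
]

#: published asymptotic Zivot-Andrews critical values (1%, 5%, 10%) per model
ZA_CRITICAL_VALUES = {
    "intercept": (-5.34, -4.80, -4.58),
    "trend": (-4.93, -4.42, -4.11),
    "both": (-5.57, -5.08, -4.82),
}

_LEVELS = ("1%", "5%", "10%")


@dataclass(frozen=True)
class UnitRootSpec:
    """Deterministic terms and lag policy for an ADF run.

    trend: "c" (constant) or "ct" (constant + linear trend).
    criterion: "aic", "bic", "maic" (Ng-Perron modified AIC) or "fixed".
    """

    trend: str = "c"
    max_lag: int = 0
    criterion: str = "aic"
    fixed_lag: int | None = None

    def __post_init__(self) -> None:
        if self.trend not in ("c", "ct"):
            raise ValueError("trend must be 'c' or 'ct'")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.criterion not in ("aic", "bic", "maic", "fixed"):
            raise ValueError("criterion must be aic, bic, maic or fixed")
        if self.criterion == "fixed":
            if self.fixed_lag is None or not 0 <= self.fixed_lag <= self.max_lag:
                raise ValueError("criterion='fixed' needs 0 <= fixed_lag <= max_lag")


@dataclass(frozen=True)
class UnitRootResult:
    tau: float                       # t-ratio of the lagged-level coefficient
    gamma: float                     # coefficient on y_{t-1}
    intercept: float
    trend_coef: float | None
    lags_used: int
    criticals: dict[str, float]
    p_value: float | None
    reject_at: str | None            # strictest level at which H0 is rejected
    break_year: int | None = None
    break_intercept: float | None = None  # theta, intercept-shift coefficient
    break_trend: float | None = None      # delta, trend-slope-shift coefficient
    nobs: int = 0


def _reject_level(tau: float, criticals: dict[str, float]) -> str | None:
    for level in _LEVELS:
        if tau < criticals[level]:
            return level
    return None


def _adf_fit(y: np.ndarray, trend: str, lag: int, start: int):
    """OLS of dy on deterministics, y_{t-1} and `lag` lagged differences.

    ``start`` is the first usable index of dy (>= lag), shared across lag
    candidates during selection so criteria compare like with like.
    """
    dy = np.diff(y)
    n = dy.size
    rows = np.arange(start, n)
    cols = [np.ones(rows.size)]
    if trend == "ct":
        cols.append(rows + 2.0)  # observation index of y_t in 1-based time
    cols.append(y[rows])         # y_{t-1}
    for i in range(1, lag + 1):
        cols.append(dy[rows - i])
    X = np.column_stack(cols)
    res = sm.OLS(dy[rows], X).fit()
    i_level = 2 if trend == "ct" else 1
    return res, i_level


def _maic(res, i_level: int, lag: int) -> float:
    # Ng-Perron modified AIC: penalty inflated by the level term's leverage
    nobs = res.nobs
    sigma2 = res.ssr / nobs
    ylag = res.model.exog[:, i_level]
    tau_k = res.params[i_level] ** 2 * float(ylag @ ylag) / sigma2
    return math.log(sigma2) + 2.0 * (tau_k + lag) / nobs


def adf_lag_search(y: np.ndarray, trend: str, max_lag: int):
    """Per-lag (aic, bic, maic) on the common estimation sample, lags 0..max_lag."""
    path = []
    for lag in range(max_lag + 1):
        res, i_level = _adf_fit(y, trend, lag, start=max_lag)
        path.append({"lag": lag, "aic": res.aic, "bic": res.bic,
                     "maic": _maic(res, i_level, lag)})
    return path


def adf_test(y: AnnualSeries | np.ndarray, spec: UnitRootSpec = UnitRootSpec()) -> UnitRootResult:
    """Augmented Dickey-Fuller test; H0: unit root (gamma = 0), left-tailed."""
    start_year = y.start_year if isinstance(y, AnnualSeries) else None
    yv = y.values if isinstance(y, AnnualSeries) else np.asarray(y, dtype=float)
    if yv.size < spec.max_lag + 3:
        raise ValueError("series too short for the requested lag order")
    if np.ptp(yv) == 0:
        raise ValueError("constant series has no unit-root problem to test")

    if spec.criterion == "fixed":
        lag = spec.fixed_lag
    else:
        path = adf_lag_search(yv, spec.trend, spec.max_lag)
        lag = min(path, key=lambda row: row[spec.criterion])["lag"]

    # refit at the chosen lag using every usable observation
    res, i_level = _adf_fit(yv, spec.trend, lag, start=lag)
    tau = float(res.tvalues[i_level])
    nobs = int(res.nobs)
    crit = mackinnoncrit(N=1, regression=spec.trend, nobs=nobs)
    criticals = dict(zip(_LEVELS, (float(c) for c in crit)))
    return UnitRootResult(
        tau=tau,
        gamma=float(res.params[i_level]),
        intercept=float(res.params[0]),
        trend_coef=float(res.params[1]) if spec.trend == "ct" else None,
        lags_used=lag,
        criticals=criticals,
        p_value=float(mackinnonp(tau, regression=spec.trend, N=1)),
        reject_at=_reject_level(tau, criticals),
        nobs=nobs,
    )


def _za_fit(y: np.ndarray, model: str, tb: int, lag: int):
    """ZA regression with a break after 1-based position ``tb``.

    DU_t = 1{t > tb}; DT_t = (t - tb) 1{t > tb}; t runs 1..n over the series.
    """
    dy = np.diff(y)
    n = dy.size
    rows = np.arange(lag, n)
    t_index = rows + 2.0  # 1-based time of y_t in the dy regression
    cols = [np.ones(rows.size)]
    slices = {"const": 0}
    j = 1
    if model in ("intercept", "both"):
        cols.append((t_index > tb).astype(float))
        slices["du"] = j
        j += 1
    if model in ("trend", "both"):
        cols.append(np.where(t_index > tb, t_index - tb, 0.0))
        slices["dt"] = j
        j += 1
    cols.append(t_index)
    slices["trend"] = j
    j += 1
    cols.append(y[rows])
    slices["level"] = j
    for i in range(1, lag + 1):
        cols.append(dy[rows - i])
    X = np.column_stack(cols)
    res = sm.OLS(dy[rows], X).fit()
    return res, slices


def za_test(y: AnnualSeries | np.ndarray, model: str = "trend", max_lag: int = 0,
            selection: str = "aic", trim: float = 0.15) -> UnitRootResult:
    """Zivot-Andrews unit-root test with one endogenous structural break.

    ``model`` picks the break form ("intercept", "trend" or "both");
    ``selection`` locates the break date by regression-AIC minimization
    ("aic") or by the conventional most-negative test statistic ("min_t").
    Candidate break dates are restricted to the trim..(1-trim) interior.
    """
    if model not in ZA_CRITICAL_VALUES:
        raise ValueError(f"model must be one of {tuple(ZA_CRITICAL_VALUES)}")
    if selection not in ("aic", "min_t"):
        raise ValueError("selection must be 'aic' or 'min_t'")
    start_year = y.start_year if isinstance(y, AnnualSeries) else None
    yv = y.values if isinstance(y, AnnualSeries) else np.asarray(y, dtype=float)
    n = yv.size
    lo, hi = int(math.ceil(trim * n)), int(math.floor((1 - trim) * n))
    if n < 15 or lo >= hi:
        raise ValueError("series too short for a trimmed break search")
    if np.ptp(yv) == 0:
        raise ValueError("constant series has no unit-root problem to test")

    best = None  # (score, tb, lag, res, slices)
    for tb in range(lo, hi + 1):
        for lag in range(max_lag + 1):
            res, slices = _za_fit(yv, model, tb, lag)
            tau = float(res.tvalues[slices["level"]])
            score = float(res.aic) if selection == "aic" else tau
            if best is None or score < best[0]:
                best = (score, tb, lag, res, slices)

    _, tb, lag, res, slices = best
    tau = float(res.tvalues[slices["level"]])
    criticals = dict(zip(_LEVELS, ZA_CRITICAL_VALUES[model]))
    return UnitRootResult(
        tau=tau,
        gamma=float(res.params[slices["level"]]),
        intercept=float(res.params[slices["const"]]),
        trend_coef=float(res.params[slices["trend"]]),
        lags_used=lag,
        criticals=criticals,
        p_value=None,
        reject_at=_reject_level(tau, criticals),
        break_year=(start_year + tb - 1) if start_year is not None else tb,
        break_intercept=float(res.params[slices["du"]]) if "du" in slices else None,
        break_trend=float(res.params[slices["dt"]]) if "dt" in slices else None,
        nobs=int(res.nobs),
    )
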