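"""Gompertz and Pearl (logistic) growth curves and their log-linearized fits.

The development-stage model is a Gompertz curve

    y(x) = a * exp(-b * exp(-c * x)),    a, b, c > 0,

an asymmetric S-curve whose inflection ordinate is a/e. The symmetric Pearl
comparator is the logistic y(x) = a / (1 + b * exp(-c * x)), inflecting at
a/2. Both are fitted after log-linearization: with the asymptote a known,

    Z(x) = ln(a) - ln(y)  =  b * exp(-c * x)   =>   ln Z = ln b - c x

is an ordinary least-squares problem. In the stage model the regressor x is
the urbanization rate (percent) and Z is built from a proxy target — the
headroom-corrected sample maximum of the GDP growth rate minus each year's
observed rate — so that Z stays strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .series_io import AnnualSeries

__all__ = [
    "GompertzParams",
    "PearlParams",
    "ProxySeries",
    "FitDiagnostics",
    "DMResult",
    "LoglinearFit",
    "gompertz_eval",
    "gompertz_inflection",
    "pearl_eval",
    "build_proxy",
    "fit_loglinear",
    "assemble_gompertz",
    "pearl_fit",
    "diagnostics",
    "dm_test",
    "compare_models",
]


@dataclass(frozen=True)
class GompertzParams:
    a: float  # upper asymptote, units of y
    b: float  # displacement (horizontal shift)
    c: float  # growth rate (steepness)

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("Gompertz parameters a, b, c must all be positive")


@dataclass(frozen=True)
class PearlParams:
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("Pearl parameters a, b, c must all be positive")


def gompertz_eval(x, p: GompertzParams):
    """Evaluate the Gompertz curve; strictly increasing, bounded in (0, a)."""
    x = np.asarray(x, dtype=float)
    out = p.a * np.exp(-p.b * np.exp(-p.c * x))
    return float(out) if out.ndim == 0 else out


def gompertz_inflection(p: GompertzParams) -> tuple[float, float]:
    """(x, y) of the inflection point: x = ln(b)/c, y = a/e."""
    return math.log(p.b) / p.c, p.a / math.e


def pearl_eval(x, p: PearlParams):
    """Evaluate the logistic (Pearl) curve; symmetric about y = a/2."""
    x = np.asarray(x, dtype=float)
    out = p.a / (1.0 + p.b * np.exp(-p.c * x))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProxySeries:
    """Positive proxy target Z per year plus the corrected maximum it uses."""

    start_year: int
    z: np.ndarray
    x_max_corrected: float

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if np.any(z <= 0):
            raise ValueError("proxy values must be strictly positive")
        z = z.copy()
        z.setflags(write=False)
        object.__setattr__(self, "z", z)


def build_proxy(g: AnnualSeries, headroom: float = 1.1,
                max_decimals: int | None = None) -> ProxySeries:
    """Z_t = headroom * max(g) - g_t, strictly positive when headroom > 1.

    ``max_decimals`` optionally rounds the sample maximum before applying the
    headroom factor; the bundled replication run uses 2, matching the
    published corrected maximum 31.504 = 1.1 x 28.64.
    """
    if len(g) == 0:
        raise ValueError("empty series")
    gmax = float(np.max(g.values))
    if max_decimals is not None:
        gmax = round(gmax, max_decimals)
    x_max = headroom * gmax
    z = x_max - g.values
    if np.any(z <= 0):
        raise ValueError(
            "headroom leaves non-positive proxy values; use headroom > 1")
    return ProxySeries(g.start_year, z, x_max)


@dataclass(frozen=True)
class FitDiagnostics:
    r2: float
    rmse: float
    mae: float
    max_ae: float
    aic: float
    bic: float
    n: int


def diagnostics(obs, pred, k: int) -> FitDiagnostics:
    """Goodness-of-fit summary with Gaussian concentrated-likelihood AIC/BIC:

    AIC = n ln(RSS/n) + 2k,  BIC = n ln(RSS/n) + k ln(n).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-D and equally long")
    n = obs.size
    resid = obs - pred
    rss = float(resid @ resid)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)
    with np.errstate(divide="ignore"):
        log_rss_n = math.log(rss / n) if rss > 0 else -math.inf
    return FitDiagnostics(
        r2=r2,
        rmse=math.sqrt(rss / n),
        mae=float(np.mean(np.abs(resid))),
        max_ae=float(np.max(np.abs(resid))),
        aic=n * log_rss_n + 2 * k,
        bic=n * log_rss_n + k * math.log(n),
        n=n,
    )


@dataclass(frozen=True)
class LoglinearFit:
    """OLS fit of ln Z = ln b - c x."""

    b: float
    c: float
    se_log_b: float   # standard error of the intercept ln b
    se_c: float       # standard error of the slope magnitude c
    diag_log: FitDiagnostics    # on the ln Z scale (the regression scale)
    diag_back: FitDiagnostics   # on the back-transformed Z scale


def _as_values(x) -> np.ndarray:
    if isinstance(x, AnnualSeries):
        return x.values
    if isinstance(x, ProxySeries):
        return x.z
    return np.asarray(x, dtype=float)


def fit_loglinear(x, z) -> LoglinearFit:
    """Least squares of ln(z) on x; returns b = exp(intercept), c = -slope.

    Note the sign convention: a proxy Z that *decays* in x yields c > 0,
    the admissible Gompertz regime. A negative fitted c is reported as-is
    (assembling GompertzParams from it will then fail validation).
    """
    xv, zv = _as_values(x), _as_values(z)
    if xv.shape != zv.shape or xv.ndim != 1:
        raise ValueError("x and z must be 1-D and equally long")
    if xv.size < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any(zv <= 0):
        raise ValueError("z must be strictly positive for the log transform")
    if np.ptp(xv) == 0:
        raise ValueError("constant regressor: x has no variation")
    lnz = np.log(zv)
    res = sm.OLS(lnz, sm.add_constant(xv)).fit()
    intercept, slope = res.params
    b, c = math.exp(intercept), -slope
    zhat = b * np.exp(-c * xv)
    return LoglinearFit(
        b=b, c=c,
        se_log_b=float(res.bse[0]), se_c=float(res.bse[1]),
        diag_log=diagnostics(lnz, res.fittedvalues, k=2),
        diag_back=diagnostics(zv, zhat, k=2),
    )


def assemble_gompertz(fit: LoglinearFit, a: float) -> GompertzParams:
    """Package a log-linear fit with an externally supplied asymptote a.

    The stage model supplies the observed sample maximum of the proxy target
    (not the headroom-corrected value) as the saturation level.
    """
    if a <= 0:
        raise ValueError("asymptote a must be positive")
    return GompertzParams(a=a, b=fit.b, c=fit.c)


def pearl_fit(x, y, a: float | None = None,
              grid: np.ndarray | None = None) -> tuple[PearlParams, FitDiagnostics]:
    """Fit the logistic comparator by linearization ln(a/y - 1) = ln b - c x.

    With ``a`` given the fit is a single OLS; otherwise ``a`` is profiled
    over a grid (default 200 points spanning just above max(y) to 3 max(y)),
    picking the value minimizing RSS on the original y scale.
    """
    xv, yv = _as_values(x), _as_values(y)
    if xv.size < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any(yv <= 0):
        raise ValueError("y must be positive")

    def _fit_given_a(a_val: float):
        if np.any(yv >= a_val):
            raise ValueError("all y must lie strictly below the asymptote a")
        w = np.log(a_val / yv - 1.0)
        res = sm.OLS(w, sm.add_constant(xv)).fit()
        b, c = math.exp(res.params[0]), -res.params[1]
        p = PearlParams(a=a_val, b=b, c=c) if b > 0 and c > 0 else None
        pred = a_val / (1.0 + b * np.exp(-c * xv))
        rss = float(np.sum((yv - pred) ** 2))
        return p, pred, rss

    if a is not None:
        p, pred, _ = _fit_given_a(a)
        if p is None:
            raise ValueError("linearized fit produced non-positive b or c")
        return p, diagnostics(yv, pred, k=3)

    ymax = float(np.max(yv))
    if grid is None:
        grid = ymax * np.linspace(1.001, 3.0, 200)
    best = None
    for a_val in np.asarray(grid, dtype=float):
        if a_val <= ymax:
            continue
        p, pred, rss = _fit_given_a(a_val)
        if p is not None and (best is None or rss < best[2]):
            best = (p, pred, rss)
    if best is None:
        raise ValueError("no admissible asymptote found on the grid")
    p, pred, _ = best
    return p, diagnostics(yv, pred, k=3)


@dataclass(frozen=True)
class DMResult:
    """Diebold-Mariano equal-predictive-accuracy test on a loss differential."""

    statistic: float
    p_value: float
    loss: str
    undefined: bool = False


def dm_test(err1, err2, loss: str = "squared") -> DMResult:
    """DM test with lag-window 0 (one-step forecast errors).

    The statistic is mean(d) / sqrt(var0(d)/n) on the loss differential
    d_t = L(e1_t) - L(e2_t); a zero-variance differential (e.g. identical
    predictions) is flagged undefined rather than reported as a number.
    """
    e1 = np.asarray(err1, dtype=float)
    e2 = np.asarray(err2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1:
        raise ValueError("error vectors must be 1-D and equally long")
    if loss == "squared":
        d = e1 ** 2 - e2 ** 2
    elif loss == "absolute":
        d = np.abs(e1) - np.abs(e2)
    else:
        raise ValueError(f"unknown loss {loss!r}")
    n = d.size
    var0 = float(np.mean((d - d.mean()) ** 2))
    if var0 == 0.0:
        return DMResult(math.nan, math.nan, loss, undefined=True)
    stat = float(d.mean() / math.sqrt(var0 / n))
    p = 2.0 * stats.norm.sf(abs(stat))
    return DMResult(stat, float(p), loss)


def compare_models(obs, pred_1, pred_2, k_1: int, k_2: int,
                   loss: str = "squared") -> tuple[FitDiagnostics, FitDiagnostics, DMResult]:
    """Side-by-side diagnostics for two candidate curves plus a DM test."""
    obs = np.asarray(obs, dtype=float)
    p1 = np.asarray(pred_1, dtype=float)
    p2 = np.asarray(pred_2, dtype=float)
    if not (obs.shape == p1.shape == p2.shape) or obs.ndim != 1 or obs.size < 3:
        raise ValueError("need three equally long 1-D vectors of length >= 3")
    return (diagnostics(obs, p1, k_1),
            diagnostics(obs, p2, k_2),
            dm_test(obs - p1, obs - p2, loss=loss))
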