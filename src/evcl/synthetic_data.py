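"""Seeded generators emulating the statistical structure of the county data.

Each generator is a closed loop with one estimation stage of the pipeline:

* an S-shaped urbanization trajectory (Gompertz in time, values in (0,1),
  noise on the logit scale) with an optional one-time slope break — the
  input the Zivot-Andrews search and the gray forecaster expect;
* a stationary AR(1) GDP-growth series fluctuating around a mean — the
  proxy target the ADF test should call stationary;
* a sequence satisfying the gray difference equation exactly, so a GM(1,1)
  fit recovers its generating parameters to machine precision;
* exact-form proxy pairs z = b*exp(-c*x)*exp(eps) for the log-linear fit.

A single integer seed drives every generator through deterministic
per-operation substreams (``default_rng([seed, op_id])``), so a run is
reproducible from one number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .growth_models import GompertzParams
from .series_io import AnnualSeries

__all__ = [
    "SimConfig",
    "gen_urbanization",
    "gen_gdp_growth",
    "gen_gray_series",
    "gen_proxy_pair",
]

# per-operation substream identifiers
_OP_URBAN, _OP_GDP, _OP_GRAY = 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: 44 years from 1979, a mid-sample slope break
    available on request, GDP growth averaging ~11.5% with mild persistence,
    and the gray series in the growth regime of a rising urban share."""

    n_years: int = 44
    start_year: int = 1979
    seed: int = 0
    # urbanization trajectory (fraction scale) + logit-scale noise
    urban_a: float = 0.6
    urban_b: float = 2.2
    urban_c: float = 0.05
    urban_noise_sd: float = 0.03
    break_year: int | None = None
    break_slope: float = 0.0          # added logit slope per year past the break
    # GDP growth AR(1) (fraction scale)
    gdp_mean: float = 0.115
    gdp_rho: float = 0.3
    gdp_sd: float = 0.055
    # gray difference equation
    gray_a: float = -0.05
    gray_b: float = 0.1
    gray_x0: float = 0.15

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if abs(self.gdp_rho) >= 1:
            raise ValueError("gdp AR(1) coefficient must satisfy |rho| < 1")
        if self.urban_noise_sd < 0 or self.gdp_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 < self.urban_a < 1:
            raise ValueError("urban asymptote must lie in (0, 1)")


def _rng(cfg_seed: int, op: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, op])


def gen_urbanization(cfg: SimConfig) -> AnnualSeries:
    """Gompertz-in-time urban share with optional slope break, fraction scale.

    With zero noise and no break the output is the exact trajectory
    a*exp(-b*exp(-c*t)); break and noise act on the logit scale so values
    stay inside (0, 1).
    """
    t = np.arange(cfg.n_years, dtype=float)
    base = cfg.urban_a * np.exp(-cfg.urban_b * np.exp(-cfg.urban_c * t))
    shift = np.zeros_like(t)
    if cfg.break_year is not None:
        tb = cfg.break_year - cfg.start_year
        if not 0 <= tb < cfg.n_years:
            raise ValueError("break_year outside the simulated span")
        shift = np.where(t > tb, (t - tb) * cfg.break_slope, 0.0)
    if cfg.urban_noise_sd == 0 and cfg.break_year is None:
        values = base
    else:
        eps = (_rng(cfg.seed, _OP_URBAN).standard_normal(cfg.n_years)
               * cfg.urban_noise_sd)
        values = expit(logit(base) + shift + eps)
    if np.any(values <= 0) or np.any(values >= 1):
        raise ValueError("simulated urban shares left the open interval (0, 1)")
    return AnnualSeries(cfg.start_year, values, units="fraction")


def gen_gdp_growth(cfg: SimConfig) -> AnnualSeries:
    """Stationary AR(1) growth-rate series around ``gdp_mean`` (fraction).

    y_t = mu + rho (y_{t-1} - mu) + eps_t, initialized from the stationary
    distribution so the whole sample shares one marginal law.
    """
    rng = _rng(cfg.seed, _OP_GDP)
    y = np.empty(cfg.n_years)
    if cfg.gdp_sd == 0:
        y.fill(cfg.gdp_mean)
    else:
        y[0] = cfg.gdp_mean + rng.standard_normal() * cfg.gdp_sd / math.sqrt(
            1.0 - cfg.gdp_rho ** 2)
        eps = rng.standard_normal(cfg.n_years) * cfg.gdp_sd
        for i in range(1, cfg.n_years):
            y[i] = cfg.gdp_mean + cfg.gdp_rho * (y[i - 1] - cfg.gdp_mean) + eps[i]
    return AnnualSeries(cfg.start_year, y, units="fraction")


def gen_gray_series(cfg: SimConfig) -> AnnualSeries:
    """Sequence satisfying the discrete gray difference equation exactly.

    Starting from x0(1), each term solves x0(k) + a*z1(k) = b with the
    background value z1(k) = x1(k-1) + x0(k)/2, which gives the recursion
    x0(k) = (b - a*x1(k-1)) / (1 + a/2) and a constant one-step ratio
    (2-a)/(2+a) ~= e^{-a}. Because the least-squares system of the GM(1,1)
    fit is built from exactly this equation, fitting the output recovers
    (a, b) to machine precision — the continuous-time restored form does
    not have this property (its residuals close only to O(a^2)).
    """
    if cfg.gray_a == 0.0:
        raise ValueError("gray development coefficient a must be nonzero")
    if cfg.gray_a == -2.0:
        raise ValueError("a = -2 makes the background recursion singular")
    if cfg.gray_x0 <= 0:
        raise ValueError("gray series must start positive")
    values = np.empty(cfg.n_years)
    values[0] = cfg.gray_x0
    x1 = cfg.gray_x0
    for k in range(1, cfg.n_years):
        values[k] = (cfg.gray_b - cfg.gray_a * x1) / (1.0 + cfg.gray_a / 2.0)
        x1 += values[k]
    if np.any(values <= 0):
        raise ValueError("gray parameters produce non-positive values")
    return AnnualSeries(cfg.start_year, values)


def gen_proxy_pair(params: GompertzParams, x_grid, noise_sd: float,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """(x, z) pairs with z = b e^{-c x} e^{eps}, eps ~ N(0, noise_sd^2).

    At zero noise ln z is exactly linear in x, so the log-linear fit is an
    exact closed loop; with noise the multiplicative error keeps z positive.
    """
    x = np.asarray(x_grid, dtype=float)
    z = params.b * np.exp(-params.c * x)
    if noise_sd > 0:
        eps = np.random.default_rng([seed, 4]).standard_normal(x.size) * noise_sd
        z = z * np.exp(eps)
    return x, z
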