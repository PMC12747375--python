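"""Development-stage coefficients and the coefficient-to-value projection.

The stage coefficient is a (0,1) multiplier scaling the full theoretical
per-hectare ecological value down to what the current institutional stage
realizes. In model mode it is the fitted Gompertz curve evaluated at the
year's urbanization rate and divided by the saturation level a, i.e.
exp(-b * exp(-c * x)); in supplied mode an externally provided coefficient
series (for instance a published table) is validated and passed through.

Projection rounding follows the reporting convention of the replication
tables: per-hectare values round half-away-from-zero to the nearest 10 CNY,
aggregate values to 2 decimal places of a million CNY.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .growth_models import GompertzParams, gompertz_eval
from .series_io import AnnualSeries, lezhi_data_path

__all__ = [
    "StageRecord",
    "EVCLRecord",
    "stage_coefficients",
    "project_evcl",
    "emit_stage_tables",
    "load_stage_csv",
    "lezhi_stage_table",
    "stages_from_table",
]


@dataclass(frozen=True)
class StageRecord:
    year: int
    urbanization: float   # fraction scale, for reporting
    coefficient: float    # strictly inside (0, 1)


@dataclass(frozen=True)
class EVCLRecord:
    year: int
    per_ha: float   # CNY/ha, rounded to the nearest 10
    total: float    # million CNY, rounded to 2 decimals


def _round_half_up(value: float, exponent: str) -> float:
    # Decimal on repr() avoids binary-float artifacts at the half boundary
    return float(Decimal(repr(value)).quantize(Decimal(exponent), rounding=ROUND_HALF_UP))


def stage_coefficients(urbanization: AnnualSeries,
                       model: GompertzParams | None = None,
                       saturation: float | None = None,
                       coefficients: Sequence[float] | None = None) -> list[StageRecord]:
    """Per-year stage coefficients, by model evaluation or pass-through.

    Model mode (``model`` given): the curve is evaluated at the urbanization
    rate on the percent scale — the scale the curve was fitted on — and
    divided by ``saturation`` (defaults to the curve's own asymptote, which
    reduces the ratio to exp(-b*exp(-c*x))).

    Supplied mode (``coefficients`` given): one coefficient per year of the
    series, validated to lie strictly inside (0, 1).
    """
    if (model is None) == (coefficients is None):
        raise ValueError("provide exactly one of model= or coefficients=")
    if urbanization.units == "percent":
        frac = urbanization.values / 100.0
        pct = urbanization.values
    else:
        frac = urbanization.values
        pct = urbanization.values * 100.0

    if model is not None:
        sat = model.a if saturation is None else saturation
        if sat <= 0:
            raise ValueError("saturation must be positive")
        coefs = np.asarray(gompertz_eval(pct, model)) / sat
    else:
        coefs = np.asarray(coefficients, dtype=float)
        if coefs.shape != urbanization.values.shape:
            raise ValueError("coefficient series must match the urbanization series")
    if np.any(coefs <= 0) or np.any(coefs >= 1):
        bad = coefs[(coefs <= 0) | (coefs >= 1)][0]
        raise ValueError(f"stage coefficient {bad} outside the open interval (0, 1)")
    years = urbanization.years
    return [StageRecord(int(y), float(f), float(c))
            for y, f, c in zip(years, frac, coefs)]


def project_evcl(stages: Sequence[StageRecord], base_per_ha: float,
                 area: float) -> list[EVCLRecord]:
    """Scale the full per-hectare value by each year's stage coefficient.

    per_ha = round-to-nearest-10(coefficient x base_per_ha);
    total (million CNY) = round2(per_ha x area / 1e6).
    """
    if base_per_ha <= 0 or area <= 0:
        raise ValueError("base_per_ha and area must be positive")
    out = []
    for s in stages:
        per_ha = _round_half_up(s.coefficient * base_per_ha / 10.0, "1") * 10.0
        total = _round_half_up(per_ha * area / 1e6, "0.01")
        out.append(EVCLRecord(year=s.year, per_ha=per_ha, total=total))
    return out


def emit_stage_tables(stages: Sequence[StageRecord], evcl: Sequence[EVCLRecord],
                      interval: int = 5) -> dict[str, pd.DataFrame]:
    """Report tables at calendar-aligned intervals plus the full annual series.

    Years divisible by ``interval`` are reported (falling back to the first
    year when none is); ``interval=1`` reports everything.
    """
    if not stages or not evcl:
        raise ValueError("empty stage or projection input")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    stage_df = pd.DataFrame([s.__dict__ for s in stages])
    evcl_df = pd.DataFrame([e.__dict__ for e in evcl])
    full = stage_df.merge(evcl_df, on="year", how="outer")
    keep = [y for y in stage_df["year"] if y % interval == 0]
    if not keep:
        keep = [int(stage_df["year"].iloc[0])]
    return {
        "stage_table": stage_df[stage_df["year"].isin(keep)].reset_index(drop=True),
        "evcl_table": evcl_df[evcl_df["year"].isin(keep)].reset_index(drop=True),
        "full_series": full,
    }


def load_stage_csv(path) -> tuple[AnnualSeries | None, pd.DataFrame]:
    """Read a ``year,urbanization,coefficient`` CSV.

    Returns the raw frame plus, when the years happen to be consecutive, an
    urbanization AnnualSeries; interval tables (e.g. 5-yearly) come back
    with ``None`` for the series and are consumed row-wise instead.
    """
    df = pd.read_csv(path)
    for col in ("year", "urbanization", "coefficient"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    df = df.sort_values("year").reset_index(drop=True)
    series = None
    years = df["year"].to_numpy(dtype=int)
    if years.size and np.all(np.diff(years) == 1):
        series = AnnualSeries(int(years[0]), df["urbanization"].to_numpy(float),
                              units="fraction")
    return series, df


def lezhi_stage_table() -> pd.DataFrame:
    """The bundled 5-yearly 1980-2050 stage-coefficient table (fractions)."""
    _, df = load_stage_csv(lezhi_data_path("lezhi_stage_coefficients.csv"))
    return df


def stages_from_table(df: pd.DataFrame) -> list[StageRecord]:
    """Row-wise supplied-mode records from a stage-coefficient frame."""
    coefs = df["coefficient"].to_numpy(float)
    if np.any(coefs <= 0) or np.any(coefs >= 1):
        raise ValueError("supplied coefficients must lie strictly inside (0, 1)")
    return [StageRecord(int(r.year), float(r.urbanization), float(r.coefficient))
            for r in df.itertuples()]
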