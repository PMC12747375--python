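"""Year-indexed annual series: container, CSV I/O and the bundled county fixture.

Every stage of the pipeline (valuation inputs aside) consumes contiguous
annual series — an urbanization rate and a GDP growth rate per calendar year.
The container deliberately stores a start year plus a dense value vector
rather than an arbitrary index: gap-free coverage is an assumption of both
the unit-root regressions and the gray forecaster, so it is enforced at
construction time instead of being re-checked downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AnnualSeries",
    "read_annual_series",
    "write_annual_series",
    "rescale",
    "lezhi_series",
    "lezhi_data_path",
]

#: recognised values for the ScaleMode units tag handled by :func:`rescale`
SCALE_MODES = ("fraction", "percent")


@dataclass(frozen=True)
class AnnualSeries:
    """A gap-free run of annual observations.

    Parameters
    ----------
    start_year : first calendar year covered.
    values : one value per consecutive year, all finite.
    units : free-text tag; ``"fraction"`` and ``"percent"`` get special
        treatment in :func:`rescale`, anything else (e.g. ``"CNY"``) is
        carried along untouched.
    """

    start_year: int
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("AnnualSeries requires a 1-D vector of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError("AnnualSeries values must all be finite")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start_year", int(self.start_year))

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_year(self) -> int:
        return self.start_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + len(self))

    def value(self, year: int) -> float:
        if not self.start_year <= year <= self.end_year:
            raise KeyError(f"year {year} outside [{self.start_year}, {self.end_year}]")
        return float(self.values[year - self.start_year])

    def window(self, first: int, last: int) -> "AnnualSeries":
        """Sub-series covering ``first..last`` inclusive."""
        if first > last:
            raise ValueError("window requires first <= last")
        if first < self.start_year or last > self.end_year:
            raise ValueError(
                f"window [{first}, {last}] outside [{self.start_year}, {self.end_year}]"
            )
        i, j = first - self.start_year, last - self.start_year + 1
        return AnnualSeries(first, self.values[i:j], self.units)

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, name: self.values})

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"))


def _check_years(years: np.ndarray) -> None:
    uniq, counts = np.unique(years, return_counts=True)
    dupes = uniq[counts > 1]
    if dupes.size:
        raise ValueError(f"duplicate year {int(dupes[0])} in input")
    gaps = np.flatnonzero(np.diff(uniq) != 1)
    if gaps.size:
        missing = int(uniq[gaps[0]]) + 1
        raise ValueError(f"missing year {missing}: years must be consecutive")


def read_annual_series(path, column: str, units: str = "") -> AnnualSeries:
    """Read one named column of a ``year,...`` CSV into an :class:`AnnualSeries`.

    Rows may arrive unsorted; duplicate or missing years raise a
    ``ValueError`` naming the offending year.
    """
    df = pd.read_csv(path)
    for col in ("year", column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    df = df.sort_values("year")
    years = df["year"].to_numpy(dtype=int)
    _check_years(years)
    return AnnualSeries(int(years[0]), df[column].to_numpy(dtype=float), units)


def write_annual_series(series: AnnualSeries, path, column: str = "value",
                        decimals: int | None = None) -> None:
    """Write a ``year,<column>`` CSV; ``decimals`` fixes the printed precision."""
    df = series.to_frame(column)
    fmt = None if decimals is None else f"%.{decimals}f"
    df.to_csv(path, index=False, float_format=fmt)


def rescale(series: AnnualSeries, target: str) -> AnnualSeries:
    """Convert between the ``fraction`` and ``percent`` scale modes.

    Idempotent when the series is already on the target scale.
    """
    if target not in SCALE_MODES:
        raise ValueError(f"target must be one of {SCALE_MODES}, got {target!r}")
    if series.units not in SCALE_MODES:
        raise ValueError(
            f"series units {series.units!r} is not a scale mode; expected one of {SCALE_MODES}"
        )
    if series.units == target:
        return series
    factor = 100.0 if target == "percent" else 0.01
    return AnnualSeries(series.start_year, series.values * factor, target)


def lezhi_data_path(name: str):
    """Path-like handle to a bundled data file (context-manager free for CSV use)."""
    return importlib.resources.files("evcl") / "data" / name


def lezhi_series(column: str = "urbanization_rate") -> AnnualSeries:
    """The bundled 1979-2022 Lezhi County series, on the percent scale.

    ``column`` is ``"urbanization_rate"`` or ``"gdp_growth_rate"``.
    """
    return read_annual_series(lezhi_data_path("lezhi_1979_2022.csv"), column, units="percent")
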