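"""Functional-value engine for the one-year ecological value of cultivated land.

Four ecosystem services are monetized and summed:

* agricultural product / raw-material supply — market value of farm output;
* water conservation — paddy storage volume priced at the shadow-engineering
  reservoir cost (CNY/m3);
* carbon fixation and oxygen release — photosynthesis stoichiometry
  (1.63 t CO2 and 1.19 t O2 per t dry matter) priced at a carbon-tax rate
  and the industrial oxygen price;
* soil and water conservation — avoided erosion (opportunity cost), avoided
  nutrient loss (market value of N/P/K) and avoided reservoir siltation
  (shadow engineering).

Unit conventions
----------------
The replication convention (``convention="replication"``) mirrors the source
arithmetic literally: erosion mass enters the erosion and siltation formulas
in kilograms against a bulk density of 1.22 (a t/m3 magnitude carrying a
kg/m3 label), enters the nutrient formula in tons, and the per-square-metre
land return Pr is rounded to 6 decimal places before use. These choices are
what reproduce the published component values digit for digit; they are
recorded in the breakdown's audit trail. ``convention="si"`` computes every
term dimensionally consistently (tons throughout, bulk density read as t/m3,
Pr unrounded) for use on new study areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .series_io import lezhi_data_path

__all__ = [
    "ValuationConstants",
    "ValuationBreakdown",
    "lezhi_constants",
    "unit_return",
    "water_value",
    "carbon_oxygen_value",
    "erosion_value",
    "nutrient_value",
    "siltation_value",
    "assess",
]

WAN = 1e4  # 万元, the ten-thousand-CNY accounting unit used in reports

#: decimal places kept in Pr (CNY/m2) under the replication convention
_PR_DECIMALS = 6

_NUTRIENTS = ("N", "P", "K")


@dataclass(frozen=True)
class ValuationConstants:
    """All scalar inputs of the one-year assessment. Areas in ha, masses in t."""

    ag_output_value: float          # CNY/a
    paddy_area: float               # ha
    total_area: float               # ha
    biomass: float                  # t/a dry-matter yield
    erosion: float                  # t/a soil erosion
    storage_height: float = 0.2     # m, standard paddy storage height
    precip: float | None = None     # mm/a
    evapotrans: float | None = None  # mm/a
    water_price: float = 0.67       # CNY/m3 (shadow reservoir cost)
    co2_per_dm: float = 1.63        # t CO2 / t dry matter
    o2_per_dm: float = 1.19         # t O2 / t dry matter
    carbon_fraction: float = 0.2729  # C/CO2
    carbon_price: float = 828.0     # CNY/t CO2
    o2_price: float = 400.0         # CNY/t O2
    bulk_density: float = 1.22      # printed kg/m3 label, t/m3 magnitude
    topsoil: float = 0.2            # m
    nutrient_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"N": 0.0, "P": 0.0, "K": 0.0})
    nutrient_prices: Mapping[str, float] = field(
        default_factory=lambda: {"N": 0.0, "P": 0.0, "K": 0.0})
    silt_rate: float = 0.24         # fraction of eroded sediment silting reservoirs
    reservoir_cost: float = 0.67    # CNY/m3

    def __post_init__(self) -> None:
        for name in ("ag_output_value", "paddy_area", "total_area", "biomass",
                     "erosion", "storage_height", "water_price", "co2_per_dm",
                     "o2_per_dm", "carbon_fraction", "carbon_price", "o2_price",
                     "bulk_density", "topsoil", "silt_rate", "reservoir_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.paddy_area > self.total_area:
            raise ValueError("paddy_area cannot exceed total_area")
        for frac in (self.carbon_fraction, self.silt_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("ratio constants must lie in [0, 1]")
        for k, v in self.nutrient_fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"nutrient fraction {k} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ValuationConstants":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def lezhi_constants() -> ValuationConstants:
    """Bundled Lezhi County 2022 constants."""
    return ValuationConstants.from_yaml(lezhi_data_path("lezhi_2022.yaml"))


@dataclass(frozen=True)
class ValuationBreakdown:
    """Component values in CNY/a plus the audit trail of applied conventions."""

    v_supply: float
    v_water: float
    v_c: float
    v_o: float
    v_e: float
    v_n: float
    v_s: float
    soil_total: float
    grand_total: float
    per_ha: float
    conventions: dict = field(default_factory=dict)

    def as_wan(self) -> dict[str, float]:
        """Component table in 万元 (ten-thousand CNY), the reporting unit."""
        return {k: getattr(self, k) / WAN
                for k in ("v_supply", "v_water", "v_c", "v_o", "v_e", "v_n",
                          "v_s", "soil_total", "grand_total")}


def _ha_to_m2(ha: float) -> float:
    return ha * 1e4


def unit_return(consts: ValuationConstants) -> float:
    """Average annual land return Pr in CNY/m2, unrounded."""
    if consts.total_area <= 0:
        raise ValueError("total_area must be positive")
    return consts.ag_output_value / _ha_to_m2(consts.total_area)


def water_value(consts: ValuationConstants, mode: str = "standard") -> float:
    """Water-conservation value Vw = storage volume x shadow water price.

    ``mode="standard"`` uses the fixed national paddy storage height;
    ``mode="balance"`` derives the height from (precipitation -
    evapotranspiration) in metres and needs both climate inputs.
    """
    if mode == "standard":
        height = consts.storage_height
    elif mode == "balance":
        if consts.precip is None or consts.evapotrans is None:
            raise ValueError("balance mode needs precip and evapotrans (mm/a)")
        height = (consts.precip - consts.evapotrans) / 1000.0
        if height < 0:
            raise ValueError(
                "negative water balance; use the standard storage-height mode")
    else:
        raise ValueError(f"unknown water mode {mode!r}")
    volume = height * _ha_to_m2(consts.paddy_area)  # m3/a
    return volume * consts.water_price


def carbon_oxygen_value(consts: ValuationConstants) -> tuple[float, float]:
    """(CO2-fixation value, O2-release value) from the dry-matter yield."""
    q = consts.biomass
    v_c = q * consts.co2_per_dm * consts.carbon_fraction * consts.carbon_price
    v_o = q * consts.o2_per_dm * consts.o2_price
    return v_c, v_o


def _erosion_mass(consts: ValuationConstants, convention: str) -> float:
    if convention == "replication":
        return consts.erosion * 1000.0  # kilograms, the literal source arithmetic
    if convention == "si":
        return consts.erosion           # tons against a t/m3 density
    raise ValueError(f"unknown convention {convention!r}")


def erosion_value(consts: ValuationConstants, convention: str = "replication") -> float:
    """Avoided-erosion value Ve = E / SC / H x Pr (opportunity cost)."""
    if consts.bulk_density <= 0 or consts.topsoil <= 0:
        raise ValueError("bulk_density and topsoil must be positive")
    pr = unit_return(consts)
    if convention == "replication":
        pr = round(pr, _PR_DECIMALS)
    return _erosion_mass(consts, convention) / consts.bulk_density / consts.topsoil * pr


def nutrient_value(consts: ValuationConstants) -> float:
    """Avoided nutrient loss Vn = sum_i E x A_i x P_i, erosion mass in tons."""
    missing = [k for k in _NUTRIENTS
               if k not in consts.nutrient_fractions or k not in consts.nutrient_prices]
    if missing:
        raise ValueError(f"missing nutrient entries: {missing}")
    return sum(consts.erosion * consts.nutrient_fractions[k] * consts.nutrient_prices[k]
               for k in _NUTRIENTS)


def siltation_value(consts: ValuationConstants, convention: str = "replication") -> float:
    """Avoided siltation Vs = E / SC x silt_rate x reservoir cost."""
    if consts.bulk_density <= 0:
        raise ValueError("bulk_density must be positive")
    return (_erosion_mass(consts, convention) / consts.bulk_density
            * consts.silt_rate * consts.reservoir_cost)


def assess(consts: ValuationConstants, convention: str = "replication",
           water_mode: str = "standard") -> ValuationBreakdown:
    """Full one-year assessment; sums are exact, with no intermediate rounding
    beyond the Pr convention documented in the module docstring."""
    v_supply = consts.ag_output_value
    v_water = water_value(consts, mode=water_mode)
    v_c, v_o = carbon_oxygen_value(consts)
    v_e = erosion_value(consts, convention)
    v_n = nutrient_value(consts)
    v_s = siltation_value(consts, convention)
    soil_total = v_e + v_n + v_s
    grand_total = v_supply + v_water + (v_c + v_o) + soil_total
    return ValuationBreakdown(
        v_supply=v_supply, v_water=v_water, v_c=v_c, v_o=v_o,
        v_e=v_e, v_n=v_n, v_s=v_s,
        soil_total=soil_total, grand_total=grand_total,
        per_ha=grand_total / consts.total_area,
        conventions={
            "mass_units": "kg in erosion/siltation, t in nutrients" if convention == "replication"
                          else "t throughout, bulk density as t/m3",
            "pr_rounding": f"{_PR_DECIMALS} decimal places (CNY/m2)" if convention == "replication"
                           else "unrounded",
            "water_mode": water_mode,
            "deflator": "identity (values taken at printed constant prices)",
        },
    )
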