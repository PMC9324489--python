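"""Equivalence accounting for city-scale human evaporation.

Expresses the annual human-body evaporation volume in intuitive currencies:
the area of broadleaf (Acer truncatum) plantation with the same annual
evapotranspiration, the evaporation of urban green space, the fraction of
natural urban evapotranspiration, and multiples of the total annual water
use of reference cities.

Rounding conventions match common reporting (one decimal for km², two
decimals for percentages, nearest hundred for population densities); raw
values are always retained alongside the rounded ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ForestSpec",
    "LandUseGrid",
    "WaterUseRecord",
    "Rounded",
    "DEFAULT_FOREST",
    "DEFAULT_WATER_USE",
    "DEFAULT_GREEN_CODES",
    "forest_et_per_area",
    "equivalent_forest_area",
    "green_space_evaporation",
    "human_vs_green_ratio",
    "equivalent_population_density",
    "natural_et_fraction",
    "water_use_multiple",
]


class Rounded(NamedTuple):
    """A raw value together with its reporting-convention rounding."""

    raw: float
    value: float


@dataclass(frozen=True)
class ForestSpec:
    """Plantation forest: stem size, planting density and per-plant water use."""

    dbh_cm: float = 15.0                 # diameter at breast height
    density_per_hm2: float = 800.0       # plants per hectare
    et_per_plant_kg: float = 1667.6      # kg water per plant per year

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0 or self.density_per_hm2 < 0 or self.et_per_plant_kg < 0:
            raise ValueError("forest parameters must be non-negative (dbh positive)")


DEFAULT_FOREST = ForestSpec()

#: Land-cover class codes (WorldCover-style) counted as urban green space.
DEFAULT_GREEN_CODES = frozenset({10, 30})  # tree cover, grassland


@dataclass
class LandUseGrid:
    """Land-cover class-code grid (default 10 m cells) with a class table."""

    codes: np.ndarray
    cellsize: float = 10.0
    class_table: dict[int, str] | None = None
    green_codes: frozenset[int] = DEFAULT_GREEN_CODES

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")
        if self.class_table is None:
            self.class_table = {10: "tree_cover", 30: "grassland", 50: "built_up"}
        unknown = self.green_codes - set(self.class_table)
        if unknown:
            raise ValueError(f"green codes missing from class table: {sorted(unknown)}")

    def green_area_km2(self) -> float:
        n_green = int(np.isin(self.codes, list(self.green_codes)).sum())
        return n_green * self.cellsize**2 / 1e6


@dataclass(frozen=True)
class WaterUseRecord:
    """Total annual water use of a reference city, million m³."""

    city: str
    country: str
    use_million_m3: float

    def __post_init__(self) -> None:
        if self.use_million_m3 <= 0:
            raise ValueError("water use must be positive")


DEFAULT_WATER_USE = (
    WaterUseRecord("Kronoberg", "Sweden", 17.42),
    WaterUseRecord("Esbjerg", "Denmark", 14.30),
    WaterUseRecord("Aust-Agder", "Norway", 15.67),
    WaterUseRecord("Tartu", "Estonia", 6.75),
)


def forest_et_per_area(spec: ForestSpec = DEFAULT_FOREST) -> float:
    """Forest evapotranspiration per unit area, m³/km²/year.

    per-plant kg/year × plants/hm² × 100 hm²/km² ÷ 1000 kg/m³.
    """
    return spec.et_per_plant_kg * spec.density_per_hm2 * 100.0 / 1000.0


def equivalent_forest_area(total_m3: float, per_area_m3_km2: float) -> Rounded:
    """Forest area (km²) with annual evapotranspiration equal to ``total_m3``."""
    if per_area_m3_km2 <= 0:
        raise ValueError("per-area evapotranspiration must be positive")
    raw = total_m3 / per_area_m3_km2
    return Rounded(raw, round(raw, 1))


def green_space_evaporation(
    grid: LandUseGrid, per_area_m3_km2: float = forest_et_per_area()
) -> float:
    """Annual evaporation of the grid's green space, m³.

    Assumes the green space is planted at the reference forest's rate:
    green-cell area (km²) × per-area evapotranspiration.
    """
    return grid.green_area_km2() * per_area_m3_km2


def human_vs_green_ratio(human_m3: float, green_m3: float) -> Rounded:
    """Human-body evaporation as a percentage of green-space evaporation."""
    if green_m3 <= 0:
        raise ValueError("green-space evaporation must be positive")
    raw = 100.0 * human_m3 / green_m3
    return Rounded(raw, round(raw, 2))


def equivalent_population_density(
    current_density: float, green_m3: float, human_m3: float
) -> Rounded:
    """Population density at which human evaporation equals green-space evaporation.

    Human evaporation scales linearly with population, so the parity density
    is current density × green/human, rounded to the nearest hundred.
    """
    if human_m3 <= 0:
        raise ValueError("human evaporation must be positive")
    raw = current_density * green_m3 / human_m3
    return Rounded(raw, round(raw / 100.0) * 100.0)


def natural_et_fraction(human_mm: float, natural_mm: float) -> Rounded:
    """Human evaporation as a percentage of natural evapotranspiration.

    Rounded to the nearest integer percent per the usual reporting style.
    """
    if natural_mm <= 0:
        raise ValueError("natural evapotranspiration must be positive")
    raw = 100.0 * human_mm / natural_mm
    return Rounded(raw, float(round(raw)))


def water_use_multiple(total_million_m3: float, record: WaterUseRecord) -> float:
    """Annual human evaporation as a multiple of a city's total water use."""
    return total_million_m3 / record.use_million_m3
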