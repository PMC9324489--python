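"""Spatial upscaling: per-person rates × population raster → district/city totals.

The per-person seasonal evaporation is spatially uniform (one representative
person); spatial structure comes entirely from the persons-per-cell
population raster. District volumes are population × per-person litres,
converted to m³; per-cell intensities are expressed as mm/year over the cell
area (1 mm over 1 km² ≡ 1000 m³).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import SEASONS

__all__ = [
    "PopulationRaster",
    "DistrictMap",
    "CityResult",
    "district_totals",
    "intensity_raster",
    "unit_area_intensity",
    "annual_city_total",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationRaster:
    """Persons-per-cell grid (row-major, north-up).

    Cell values are persons in the cell, not a density. Cells equal to
    ``nodata`` are treated as zero population (with a logged warning).
    """

    data: np.ndarray
    cellsize: float = 100.0            # metres
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("population raster must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")
        mask = self.data == self.nodata
        if mask.any():
            logger.warning(
                "population raster: %d nodata cells treated as zero population",
                int(mask.sum()),
            )
            self.data = np.where(mask, 0.0, self.data)
        if (self.data < 0).any():
            raise ValueError("populated cells must be non-negative")

    @property
    def cell_area_m2(self) -> float:
        return self.cellsize**2

    def total_population(self) -> float:
        return float(self.data.sum())


@dataclass
class DistrictMap:
    """Integer district labels aligned to a population raster."""

    labels: np.ndarray
    names: dict[int, str]
    cellsize: float = 100.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("district label grid must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("district labels must be integers")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def areas_km2(self) -> dict[int, float]:
        """District areas from the label grid, km²."""
        labels, counts = np.unique(self.labels, return_counts=True)
        cell_km2 = self.cellsize**2 / 1e6
        return {int(l): float(c) * cell_km2 for l, c in zip(labels, counts)}


@dataclass
class CityResult:
    """District × season evaporation volumes with populations.

    ``table`` is tidy with columns (district, season, population, volume_m3).
    """

    table: pd.DataFrame
    per_person_litres: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"district", "season", "population", "volume_m3"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"result table must contain columns {sorted(required)}")
        if (self.table["volume_m3"] < 0).any():
            raise ValueError("volumes must be non-negative")

    def seasons(self) -> list[str]:
        return sorted(self.table["season"].unique().tolist())

    def city_seasonal_totals(self) -> dict[str, float]:
        g = self.table.groupby("season")["volume_m3"].sum()
        return {str(k): float(v) for k, v in g.items()}

    def district_annual_totals(self) -> dict[str, float]:
        g = self.table.groupby("district")["volume_m3"].sum()
        return {str(k): float(v) for k, v in g.items()}

    def city_total(self) -> float:
        return float(self.table["volume_m3"].sum())


def district_totals(
    per_person: dict[str, float],
    districts: DistrictMap,
    pop: PopulationRaster,
) -> CityResult:
    """District evaporation volumes, m³, per season.

    ``per_person`` maps season → litres/person/season. District volume is
    (district population × per-person litres)/1000.
    """
    if districts.labels.shape != pop.data.shape:
        raise ValueError(
            f"district grid {districts.labels.shape} misaligned with "
            f"population raster {pop.data.shape}"
        )
    labels = districts.labels.ravel()
    weights = pop.data.ravel()
    counts = np.bincount(labels, weights=weights)
    rows = []
    for label, name in sorted(districts.names.items()):
        district_pop = float(counts[label]) if label < len(counts) else 0.0
        for season, litres in per_person.items():
            rows.append(
                {
                    "district": name,
                    "season": season,
                    "population": district_pop,
                    "volume_m3": district_pop * litres / 1000.0,
                }
            )
    return CityResult(pd.DataFrame(rows), per_person_litres=dict(per_person))


def intensity_raster(pop: PopulationRaster, per_person_annual: float) -> np.ndarray:
    """Per-cell evaporation intensity, mm/year.

    Cell volume (m³) = persons × litres/1000; intensity (mm) = volume /
    cell area (m²) × 1000. Zero exactly where population is zero.
    """
    if pop.cellsize <= 0:
        raise ValueError("cell size must be positive")
    volume_m3 = pop.data * per_person_annual / 1000.0
    return volume_m3 / pop.cell_area_m2 * 1000.0


def unit_area_intensity(total_volume_m3: float, area_km2: float) -> tuple[float, float]:
    """City-average intensity: (m³/km², mm) for a volume over an area."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    per_km2 = total_volume_m3 / area_km2
    return per_km2, per_km2 / 1000.0


def annual_city_total(result: CityResult) -> float:
    """Annual city volume, m³: sum of the four seasonal city totals."""
    present = set(result.seasons())
    missing = set(SEASONS) - present
    if missing:
        raise ValueError(f"missing seasons in result: {sorted(missing)}")
    return result.city_total()
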