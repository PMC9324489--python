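"""End-to-end orchestration: config → per-person rates → city results.

This is the library face of the workflow the command line wraps: generate
(or load) the city and weather, integrate the per-person schedule over each
season, upscale over the population raster, and derive the comparison
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import compare as cmp
from .compare import LandUseGrid
from .config import RunConfig
from .schedule import DailyWeather, annual_person_evaporation
from .synthetic import generate_city, generate_weather
from .upscale import (
    CityResult,
    DistrictMap,
    PopulationRaster,
    annual_city_total,
    district_totals,
    intensity_raster,
    unit_area_intensity,
)

__all__ = ["PipelineResult", "run_pipeline", "comparison_report"]


@dataclass
class PipelineResult:
    per_person_litres: dict[str, float]          # per season + "annual"
    city: CityResult
    intensity_mm: np.ndarray
    annual_total_m3: float
    city_area_km2: float
    mean_intensity_mm: float
    population: float
    pop: PopulationRaster = field(repr=False, default=None)
    districts: DistrictMap = field(repr=False, default=None)
    landuse: LandUseGrid | None = field(repr=False, default=None)
    weather: dict[str, list[DailyWeather]] = field(repr=False, default_factory=dict)


def run_pipeline(
    cfg: RunConfig,
    pop: PopulationRaster | None = None,
    districts: DistrictMap | None = None,
    landuse: LandUseGrid | None = None,
    weather: dict[str, list[DailyWeather]] | None = None,
) -> PipelineResult:
    """Run the full accounting pipeline under ``cfg``.

    Inputs left as None are generated synthetically from the config's city
    and weather specs (deterministic under the config seed).
    """
    if pop is None or districts is None:
        gen_pop, gen_districts, gen_landuse = generate_city(cfg.city)
        pop = pop or gen_pop
        districts = districts or gen_districts
        landuse = landuse or gen_landuse
    if weather is None:
        weather = generate_weather(cfg.weather, cfg.year)

    per_person = annual_person_evaporation(
        weather, cfg.schedule, cfg.season_configs(), cfg.person(), cfg.constants()
    )
    seasonal = {k: v for k, v in per_person.items() if k != "annual"}
    city = district_totals(seasonal, districts, pop)
    total = annual_city_total(city)
    mm_grid = intensity_raster(pop, per_person["annual"])
    area_km2 = (
        cfg.city_area_km2
        if cfg.city_area_km2 is not None
        else pop.data.size * pop.cell_area_m2 / 1e6
    )
    _, mean_mm = unit_area_intensity(total, area_km2)
    return PipelineResult(
        per_person_litres=per_person,
        city=city,
        intensity_mm=mm_grid,
        annual_total_m3=total,
        city_area_km2=area_km2,
        mean_intensity_mm=mean_mm,
        population=pop.total_population(),
        pop=pop,
        districts=districts,
        landuse=landuse,
        weather=weather,
    )


def comparison_report(
    annual_total_m3: float,
    mean_intensity_mm: float,
    natural_et_mm: float = 348.0,
    forest: cmp.ForestSpec = cmp.DEFAULT_FOREST,
    landuse: LandUseGrid | None = None,
    water_use: tuple[cmp.WaterUseRecord, ...] = cmp.DEFAULT_WATER_USE,
) -> dict:
    """Equivalence accounting for an annual human-evaporation total.

    Returns a nested dict (raw and rounded values side by side) covering the
    forest-area equivalent, green-space parity where a land-use grid is
    given, the fraction of natural evapotranspiration, and water-use
    multiples.
    """
    per_area = cmp.forest_et_per_area(forest)
    area = cmp.equivalent_forest_area(annual_total_m3, per_area)
    et_frac = cmp.natural_et_fraction(mean_intensity_mm, natural_et_mm)
    report: dict = {
        "annual_total_m3": annual_total_m3,
        "forest_et_m3_per_km2": per_area,
        "equivalent_forest_area_km2": {"raw": area.raw, "rounded": area.value},
        "natural_et_fraction_pct": {"raw": et_frac.raw, "rounded": et_frac.value},
        "water_use_multiples": {
            rec.city: cmp.water_use_multiple(annual_total_m3 / 1e6, rec)
            for rec in water_use
        },
    }
    if landuse is not None:
        green = cmp.green_space_evaporation(landuse, per_area)
        report["green_space_m3"] = green
        if green > 0:
            ratio = cmp.human_vs_green_ratio(annual_total_m3, green)
            report["human_vs_green_pct"] = {"raw": ratio.raw, "rounded": ratio.value}
    return report
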