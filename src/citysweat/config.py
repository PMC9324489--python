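"""Run configuration: one versioned YAML document driving the whole pipeline.

Unknown keys anywhere in the document are errors, so a misspelled
model-interpretation flag cannot silently fall back to a default. All
randomness flows from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .schedule import DailySchedule, SeasonConfig, SensitivityBounds
from .synthetic import CitySpec, WeatherSpec
from .thermo import (
    DEFAULT_CONSTANTS,
    SEASONAL_CLOTHING,
    SEASONS,
    ModelConstants,
    PersonProfile,
)
from .schedule import default_season_configs

__all__ = ["RunConfig", "load_config", "CONFIG_VERSION"]

CONFIG_VERSION = 1


def _check_keys(section: str, data: dict[str, Any], allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {section}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    seed: int = 0
    year: int = 2020
    ad: float = 1.8
    icl_unit: str = "clo"
    e11_grouping: str = "divide"
    vapor_unit: str = "mmHg"
    hr: float = 4.7
    schedule: DailySchedule = field(default_factory=DailySchedule)
    city: CitySpec = field(default_factory=CitySpec)
    weather: WeatherSpec = field(default_factory=WeatherSpec)
    season_overrides: dict[str, dict[str, Any]] = field(default_factory=dict)
    sensitivity: SensitivityBounds = field(default_factory=SensitivityBounds)
    natural_et_mm: float = 348.0
    city_area_km2: float | None = None

    def constants(self) -> ModelConstants:
        return ModelConstants(
            hr=self.hr, vapor_unit=self.vapor_unit, e11_grouping=self.e11_grouping
        )

    def person(self) -> PersonProfile:
        return PersonProfile(AD=self.ad)

    def season_configs(self) -> dict[str, SeasonConfig]:
        clothing = {
            s: SEASONAL_CLOTHING[s].with_unit(
                "si" if self.icl_unit == "as_printed" else "clo"
            )
            for s in SEASONS
        }
        cfgs = default_season_configs(clothing)
        for season, over in self.season_overrides.items():
            if season not in cfgs:
                raise ValueError(f"unknown season {season!r} in overrides")
            _check_keys(
                f"seasons.{season}", over,
                {"indoor_mode", "setpoint", "clip_range", "rh"},
            )
            kwargs = dict(over)
            if "clip_range" in kwargs:
                kwargs["clip_range"] = tuple(kwargs["clip_range"])
            cfgs[season] = replace(cfgs[season], **kwargs)
        return cfgs

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": CONFIG_VERSION,
            "seed": self.seed,
            "year": self.year,
            "person": {"AD": self.ad},
            "flags": {
                "icl_unit": self.icl_unit,
                "e11_grouping": self.e11_grouping,
                "vapor_unit": self.vapor_unit,
                "hr": self.hr,
            },
            "schedule": {
                "sleep": self.schedule.hours_sleep,
                "light": self.schedule.hours_light,
                "moderate": self.schedule.hours_moderate,
            },
            "city": {
                "n_districts": self.city.n_districts,
                "total_population": self.city.total_population,
                "shape": list(self.city.shape),
                "cellsize": self.city.cellsize,
                "landuse_refine": self.city.landuse_refine,
                "green_fraction": self.city.green_fraction,
                "density_scale": self.city.density_scale,
                "density_noise": self.city.density_noise,
            },
            "weather": {
                "means": dict(self.weather.means),
                "amplitudes": dict(self.weather.amplitudes),
                "noise_sd": self.weather.noise_sd,
            },
            "seasons": self.season_overrides,
            "sensitivity": {
                "sleep": list(self.sensitivity.sleep),
                "moderate": list(self.sensitivity.moderate),
            },
            "compare": {
                "natural_et_mm": self.natural_et_mm,
                "city_area_km2": self.city_area_km2,
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        _check_keys(
            "config", data,
            {"version", "seed", "year", "person", "flags", "schedule", "city",
             "weather", "seasons", "sensitivity", "compare"},
        )
        version = data.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {version}")
        kwargs: dict[str, Any] = {
            "seed": int(data.get("seed", 0)),
            "year": int(data.get("year", 2020)),
        }
        person = data.get("person", {})
        _check_keys("person", person, {"AD"})
        kwargs["ad"] = float(person.get("AD", 1.8))
        flags = data.get("flags", {})
        _check_keys("flags", flags, {"icl_unit", "e11_grouping", "vapor_unit", "hr"})
        kwargs["icl_unit"] = flags.get("icl_unit", "clo")
        kwargs["e11_grouping"] = flags.get("e11_grouping", "divide")
        kwargs["vapor_unit"] = flags.get("vapor_unit", "mmHg")
        kwargs["hr"] = float(flags.get("hr", 4.7))
        if kwargs["icl_unit"] not in ("clo", "as_printed"):
            raise ValueError(f"unknown icl_unit {kwargs['icl_unit']!r}")
        sched = data.get("schedule", {})
        _check_keys("schedule", sched, {"sleep", "light", "moderate"})
        if sched:
            kwargs["schedule"] = DailySchedule(
                hours_sleep=float(sched.get("sleep", 8.0)),
                hours_light=float(sched.get("light", 14.0)),
                hours_moderate=float(sched.get("moderate", 2.0)),
            )
        city = data.get("city", {})
        _check_keys(
            "city", city,
            {"n_districts", "total_population", "shape", "cellsize",
             "landuse_refine", "green_fraction", "density_scale", "density_noise"},
        )
        if city:
            defaults = CitySpec()
            kwargs["city"] = CitySpec(
                n_districts=int(city.get("n_districts", defaults.n_districts)),
                total_population=int(
                    city.get("total_population", defaults.total_population)
                ),
                shape=tuple(city.get("shape", defaults.shape)),
                cellsize=float(city.get("cellsize", defaults.cellsize)),
                landuse_refine=int(city.get("landuse_refine", defaults.landuse_refine)),
                green_fraction=float(city.get("green_fraction", defaults.green_fraction)),
                density_scale=float(city.get("density_scale", defaults.density_scale)),
                density_noise=float(city.get("density_noise", defaults.density_noise)),
                seed=int(data.get("seed", 0)),
            )
        weather = data.get("weather", {})
        _check_keys("weather", weather, {"means", "amplitudes", "noise_sd"})
        if weather:
            defaults_w = WeatherSpec()
            kwargs["weather"] = WeatherSpec(
                means=dict(weather.get("means", defaults_w.means)),
                amplitudes=dict(weather.get("amplitudes", defaults_w.amplitudes)),
                noise_sd=float(weather.get("noise_sd", defaults_w.noise_sd)),
                seed=int(data.get("seed", 0)),
            )
        seasons = data.get("seasons", {}) or {}
        kwargs["season_overrides"] = {k: dict(v) for k, v in seasons.items()}
        sens = data.get("sensitivity", {})
        _check_keys("sensitivity", sens, {"sleep", "moderate"})
        if sens:
            kwargs["sensitivity"] = SensitivityBounds(
                sleep=tuple(sens.get("sleep", (6.0, 10.0))),
                moderate=tuple(sens.get("moderate", (0.5, 2.0))),
            )
        comp = data.get("compare", {})
        _check_keys("compare", comp, {"natural_et_mm", "city_area_km2"})
        kwargs["natural_et_mm"] = float(comp.get("natural_et_mm", 348.0))
        area = comp.get("city_area_km2")
        kwargs["city_area_km2"] = None if area is None else float(area)
        cfg = cls(**kwargs)
        cfg.season_configs()  # validate overrides eagerly
        return cfg

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            city=replace(self.city, seed=seed),
            weather=replace(self.weather, seed=seed),
        )


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Load a YAML config (or defaults when ``path`` is None), optionally reseeded."""
    if path is None:
        cfg = RunConfig()
    else:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config document must be a mapping")
        cfg = RunConfig.from_dict(data)
    if seed is not None:
        cfg = cfg.with_seed(seed)
    elif cfg.city.seed != cfg.seed or cfg.weather.seed != cfg.seed:
        cfg = cfg.with_seed(cfg.seed)
    return cfg
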