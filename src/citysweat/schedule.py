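"""Daily activity schedule, seasonal integration and schedule sensitivity.

A representative day is split into three indoor activity blocks — sleep,
light work and moderate work (default 8/14/2 h) — each evaluated with the
heat-balance chain at the day's indoor temperature and the season's clothing
and humidity. Daily whole-body evaporation (litres, 1 g ≡ 1 mL) sums the
blocks; seasonal and annual totals sum days.

The sensitivity analysis perturbs the time allocation within survey-based
bounds (sleep 6–10 h, moderate activity 0.5–2 h, light work the remainder)
and reports the extreme relative changes of the annual per-person total.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .thermo import (
    ACTIVITY_LEVELS,
    DEFAULT_CONSTANTS,
    SEASONAL_CLOTHING,
    SEASONS,
    ActivityLevel,
    ClothingEnsemble,
    Environment,
    ModelConstants,
    PersonProfile,
    heat_balance,
    person_evaporation_mass,
)

__all__ = [
    "DailySchedule",
    "SeasonConfig",
    "DailyWeather",
    "SensitivityBounds",
    "SensitivityResult",
    "DEFAULT_SCHEDULE",
    "DEFAULT_SEASON_CONFIGS",
    "default_season_configs",
    "season_dates",
    "indoor_temperature",
    "daily_person_evaporation",
    "seasonal_person_evaporation",
    "annual_person_evaporation",
    "schedule_sensitivity",
]

_BLOCK_ACTIVITIES = ("sleep", "light_work", "moderate_work")


@dataclass(frozen=True)
class DailySchedule:
    """Hours per activity block; must partition the 24-h day exactly."""

    hours_sleep: float = 8.0
    hours_light: float = 14.0
    hours_moderate: float = 2.0

    def __post_init__(self) -> None:
        hours = (self.hours_sleep, self.hours_light, self.hours_moderate)
        if any(h < 0 for h in hours):
            raise ValueError("block durations must be non-negative")
        if abs(sum(hours) - 24.0) > 1e-9:
            raise ValueError(f"schedule must sum to 24 h, got {sum(hours)}")

    def blocks(self) -> tuple[tuple[str, float], ...]:
        return (
            ("sleep", self.hours_sleep),
            ("light_work", self.hours_light),
            ("moderate_work", self.hours_moderate),
        )


DEFAULT_SCHEDULE = DailySchedule()


@dataclass(frozen=True)
class SeasonConfig:
    """Seasonal indoor context: clothing, indoor-temperature rule, humidity.

    ``indoor_mode`` is one of ``"follow"`` (indoor = outdoor daily mean),
    ``"fixed"`` (constant ``setpoint``) or ``"clipped"`` (outdoor mean
    bounded to ``clip_range``).
    """

    season: str
    clothing: ClothingEnsemble
    indoor_mode: str = "clipped"
    setpoint: float = 22.0
    clip_range: tuple[float, float] = (16.0, 30.0)
    rh: float = 0.5

    def __post_init__(self) -> None:
        if self.indoor_mode not in ("follow", "fixed", "clipped"):
            raise ValueError(f"unknown indoor mode {self.indoor_mode!r}")
        if not (0.0 <= self.rh <= 1.0):
            raise ValueError("relative humidity must lie in [0, 1]")
        if self.clip_range[0] > self.clip_range[1]:
            raise ValueError("clip range must be ordered")


#: Default seasonal relative humidities (dry winter, humid summer).
_DEFAULT_RH = {"spring": 0.40, "summer": 0.60, "autumn": 0.50, "winter": 0.30}


def default_season_configs(
    clothing: dict[str, ClothingEnsemble] | None = None,
) -> dict[str, SeasonConfig]:
    """Default per-season configuration.

    Winter uses a fixed 22 °C heating setpoint (district heating keeps
    indoor temperatures high regardless of outdoor cold); the other seasons
    follow the outdoor daily mean clipped to a habitable 16–30 °C indoor
    range.
    """
    clothing = clothing or SEASONAL_CLOTHING
    cfgs: dict[str, SeasonConfig] = {}
    for season in SEASONS:
        if season == "winter":
            cfgs[season] = SeasonConfig(
                season, clothing[season], indoor_mode="fixed",
                setpoint=22.0, rh=_DEFAULT_RH[season],
            )
        else:
            cfgs[season] = SeasonConfig(
                season, clothing[season], indoor_mode="clipped",
                clip_range=(16.0, 30.0), rh=_DEFAULT_RH[season],
            )
    return cfgs


DEFAULT_SEASON_CONFIGS = default_season_configs()


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather: calendar date and mean outdoor air temperature, °C."""

    date: dt.date
    tmean: float


def season_dates(year: int) -> dict[str, list[dt.date]]:
    """Meteorological-season calendar for ``year``.

    Spring Mar–May, summer Jun–Aug, autumn Sep–Nov; winter is Jan, Feb and
    December of the same calendar year, so the four seasons exactly cover
    the year (365 or 366 days).
    """
    months = {
        "spring": (3, 4, 5),
        "summer": (6, 7, 8),
        "autumn": (9, 10, 11),
        "winter": (1, 2, 12),
    }
    out: dict[str, list[dt.date]] = {}
    for season, mm in months.items():
        days: list[dt.date] = []
        for m in mm:
            ndays = calendar.monthrange(year, m)[1]
            days.extend(dt.date(year, m, d) for d in range(1, ndays + 1))
        out[season] = days
    return out


def indoor_temperature(outdoor_mean: float, cfg: SeasonConfig) -> float:
    """Map the outdoor daily mean to the indoor temperature per the season rule."""
    if cfg.indoor_mode == "fixed":
        return cfg.setpoint
    if cfg.indoor_mode == "follow":
        return outdoor_mean
    lo, hi = cfg.clip_range
    return min(max(outdoor_mean, lo), hi)


def _block_rates_g_per_h(
    ta_indoor: float,
    cfg: SeasonConfig,
    person: PersonProfile,
    constants: ModelConstants,
) -> dict[str, float]:
    """Whole-body evaporation rate (g/h) per activity at one indoor state."""
    env = Environment(ta=ta_indoor, rh=cfg.rh)
    rates = {}
    for name in _BLOCK_ACTIVITIES:
        act = ACTIVITY_LEVELS[name]
        hb = heat_balance(env, act, cfg.clothing, constants)
        rates[name] = hb.msw * person.AD
    return rates


def daily_person_evaporation(
    schedule: DailySchedule,
    day: DailyWeather,
    cfg: SeasonConfig,
    person: PersonProfile = PersonProfile(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Whole-body evaporation over one day, litres/person.

    Sums ``m_sw × A_D × hours`` over the three activity blocks at the day's
    indoor temperature (1 g of evaporated water ≡ 1 mL).
    """
    ta_in = indoor_temperature(day.tmean, cfg)
    rates = _block_rates_g_per_h(ta_in, cfg, person, constants)
    grams = sum(rates[name] * hours for name, hours in schedule.blocks())
    return grams / 1000.0


def seasonal_person_evaporation(
    days: list[DailyWeather],
    schedule: DailySchedule,
    cfg: SeasonConfig,
    person: PersonProfile = PersonProfile(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Per-person evaporation summed over a season's days, litres."""
    if not days:
        raise ValueError("season must contain at least one day")
    return sum(
        daily_person_evaporation(schedule, d, cfg, person, constants) for d in days
    )


def annual_person_evaporation(
    weather: dict[str, list[DailyWeather]],
    schedule: DailySchedule,
    cfgs: dict[str, SeasonConfig],
    person: PersonProfile = PersonProfile(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Per-person litres per season plus the ``"annual"`` sum."""
    out = {
        season: seasonal_person_evaporation(days, schedule, cfgs[season], person, constants)
        for season, days in weather.items()
    }
    out["annual"] = sum(out[s] for s in weather)
    return out


@dataclass(frozen=True)
class SensitivityBounds:
    """Survey-based bounds on the time allocation: sleep and moderate hours."""

    sleep: tuple[float, float] = (6.0, 10.0)
    moderate: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.sleep, self.moderate):
            if lo > hi or lo < 0:
                raise ValueError("bounds must be ordered and non-negative")
        worst = self.sleep[1] + self.moderate[1]
        if worst > 24.0:
            raise ValueError("bounds leave no time for light work")

    def contains(self, schedule: DailySchedule) -> bool:
        return (
            self.sleep[0] <= schedule.hours_sleep <= self.sleep[1]
            and self.moderate[0] <= schedule.hours_moderate <= self.moderate[1]
        )


@dataclass(frozen=True)
class SensitivityResult:
    min_pct: float
    max_pct: float
    baseline_litres: float
    grid: "np.ndarray" = field(repr=False)  # columns: sleep_h, moderate_h, litres, pct
    argmin: tuple[float, float] = (0.0, 0.0)
    argmax: tuple[float, float] = (0.0, 0.0)


def schedule_sensitivity(
    bounds: SensitivityBounds,
    baseline: DailySchedule,
    weather: dict[str, list[DailyWeather]],
    cfgs: dict[str, SeasonConfig],
    person: PersonProfile = PersonProfile(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
    n_sleep: int = 9,
    n_moderate: int = 7,
) -> SensitivityResult:
    """Relative change of the annual per-person total over a schedule grid.

    Evaluates a uniform ``n_sleep × n_moderate`` grid over the bounds
    (corners included; the objective is monotone in each coordinate, so the
    corners carry the extremes and the grid documents the surface). The
    baseline must lie within the bounds; because the annual total is linear
    in block hours, the baseline value is reproduced exactly by the linear
    form, so the returned range always brackets zero.
    """
    if not bounds.contains(baseline):
        raise ValueError("baseline schedule lies outside the sensitivity bounds")

    # Annual total is linear in (hours_sleep, hours_light, hours_moderate):
    # precompute per-activity annual litres-per-hour-of-activity once.
    per_act = {name: 0.0 for name in _BLOCK_ACTIVITIES}
    for season, days in weather.items():
        cfg = cfgs[season]
        for day in days:
            rates = _block_rates_g_per_h(
                indoor_temperature(day.tmean, cfg), cfg, person, constants
            )
            for name in _BLOCK_ACTIVITIES:
                per_act[name] += rates[name] / 1000.0

    def annual(sleep_h: float, moderate_h: float) -> float:
        light_h = 24.0 - sleep_h - moderate_h
        return (
            per_act["sleep"] * sleep_h
            + per_act["light_work"] * light_h
            + per_act["moderate_work"] * moderate_h
        )

    base = annual(baseline.hours_sleep, baseline.hours_moderate)
    sleeps = np.linspace(bounds.sleep[0], bounds.sleep[1], n_sleep)
    moderates = np.linspace(bounds.moderate[0], bounds.moderate[1], n_moderate)
    # baseline always belongs to the search set, so the range brackets zero
    rows = [(baseline.hours_sleep, baseline.hours_moderate, base, 0.0)]
    for s in sleeps:
        for m in moderates:
            total = annual(s, m)
            rows.append((s, m, total, 100.0 * (total - base) / base))
    grid = np.array(rows)
    imin = int(np.argmin(grid[:, 3]))
    imax = int(np.argmax(grid[:, 3]))
    return SensitivityResult(
        min_pct=float(grid[imin, 3]),
        max_pct=float(grid[imax, 3]),
        baseline_litres=base,
        grid=grid,
        argmin=(float(grid[imin, 0]), float(grid[imin, 1])),
        argmax=(float(grid[imax, 0]), float(grid[imax, 1])),
    )
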