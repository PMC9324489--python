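"""Seeded synthetic inputs: a gridded city and seasonal daily weather.

The generator emulates the shape of the real inputs the pipeline consumes —
a persons-per-cell population raster (100 m cells) with a core-peaked
density gradient, a district partition, a finer land-cover grid (10 m cells)
with a configurable green-space fraction, and four seasonal daily
mean-temperature series following a monsoon-like annual cycle (cold dry
winters near or below 0 °C, hot summers near 27 °C, annual mean ≈ 13 °C).

Everything is deterministic under the spec seed: population is allocated to
cells by largest-remainder rounding so the raster sums to the requested
total exactly, districts are Voronoi cells around seeded points with
first-index tie-breaking, and weather noise comes from one seeded generator
per call.
"""

from __future__ import annotations

import numpy as np

from .schedule import DailyWeather, season_dates
from .thermo import SEASONS
from .upscale import DistrictMap, PopulationRaster
from .compare import LandUseGrid, DEFAULT_GREEN_CODES

from dataclasses import dataclass, field

__all__ = [
    "CitySpec",
    "WeatherSpec",
    "generate_city",
    "generate_weather",
    "fixture_city_spec",
]


@dataclass(frozen=True)
class CitySpec:
    """Synthetic city layout.

    ``shape`` is the population-raster grid (rows, cols) at ``cellsize``
    metres; the land-cover grid refines each population cell by
    ``landuse_refine`` per axis (default 100 m → 10 m). ``density_scale``
    sets the e-folding length of the core-peaked density profile as a
    fraction of the grid half-extent.
    """

    n_districts: int = 16
    total_population: int = 21_890_000
    shape: tuple[int, int] = (256, 256)
    cellsize: float = 100.0
    landuse_refine: int = 10
    green_fraction: float = 0.25
    density_scale: float = 0.5
    density_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_population <= 0:
            raise ValueError("total population must be positive")
        if not (0.0 <= self.green_fraction <= 1.0):
            raise ValueError("green fraction must lie in [0, 1]")
        if self.n_districts < 1:
            raise ValueError("need at least one district")
        if self.shape[0] * self.shape[1] < self.n_districts:
            raise ValueError("grid too small for the requested district count")
        if self.landuse_refine < 1:
            raise ValueError("land-use refinement factor must be >= 1")


@dataclass(frozen=True)
class WeatherSpec:
    """Seasonal climate: per-season mean and within-season amplitude, °C."""

    means: dict[str, float] = field(
        default_factory=lambda: {
            "spring": 14.0, "summer": 27.0, "autumn": 13.0, "winter": -2.0
        }
    )
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "spring": 6.0, "summer": 3.0, "autumn": 6.0, "winter": 4.0
        }
    )
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise scale must be non-negative")
        for season in SEASONS:
            if season not in self.means or season not in self.amplitudes:
                raise ValueError(f"missing season {season!r} in weather spec")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``, exact sum.

    Floors the proportional shares and hands the remaining units to the
    largest fractional parts; ties break on the lower flat index.
    """
    shares = weights / weights.sum() * total
    floors = np.floor(shares).astype(np.int64)
    remainder = int(total - floors.sum())
    if remainder > 0:
        frac = shares - floors
        # stable sort on (-frac, index): lower index wins ties
        order = np.lexsort((np.arange(frac.size), -frac))
        floors[order[:remainder]] += 1
    return floors


def generate_city(spec: CitySpec) -> tuple[PopulationRaster, DistrictMap, LandUseGrid]:
    """Generate a deterministic synthetic city from ``spec``.

    Returns the population raster (summing exactly to the spec total), the
    Voronoi district map aligned to it, and the refined land-cover grid with
    exactly ``round(green_fraction × n_cells)`` green cells.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    yy, xx = np.mgrid[0:rows, 0:cols]

    # core-peaked density: exponential decay from the grid centre with
    # mild lognormal heterogeneity
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx)
    scale = spec.density_scale * max(rows, cols) / 2.0
    weights = np.exp(-dist / scale)
    if spec.density_noise > 0:
        weights = weights * rng.lognormal(0.0, spec.density_noise, size=weights.shape)
    pop_counts = _largest_remainder(weights.ravel(), spec.total_population)
    pop = PopulationRaster(
        pop_counts.reshape(spec.shape).astype(float), cellsize=spec.cellsize
    )

    # Voronoi districts around seeded points; argmin takes the first
    # (lowest-index) seed on exact ties
    seeds_y = rng.uniform(0, rows, spec.n_districts)
    seeds_x = rng.uniform(0, cols, spec.n_districts)
    d2 = (yy[..., None] - seeds_y) ** 2 + (xx[..., None] - seeds_x) ** 2
    labels = np.argmin(d2, axis=-1).astype(np.int64)
    names = {i: f"district_{i + 1:02d}" for i in range(spec.n_districts)}
    districts = DistrictMap(labels, names, cellsize=spec.cellsize)

    # refined land-cover grid with an exact green-cell count
    lu_shape = (rows * spec.landuse_refine, cols * spec.landuse_refine)
    n_cells = lu_shape[0] * lu_shape[1]
    n_green = int(round(spec.green_fraction * n_cells))
    codes = np.full(n_cells, 50, dtype=np.int16)  # built-up
    if n_green > 0:
        green_idx = rng.permutation(n_cells)[:n_green]
        # split green space between tree cover and grassland
        half = n_green // 2
        codes[green_idx[:half]] = 10
        codes[green_idx[half:]] = 30
    landuse = LandUseGrid(
        codes.reshape(lu_shape),
        cellsize=spec.cellsize / spec.landuse_refine,
        green_codes=DEFAULT_GREEN_CODES,
    )
    return pop, districts, landuse


def generate_weather(
    spec: WeatherSpec, year: int = 2020
) -> dict[str, list[DailyWeather]]:
    """Generate four seasonal daily mean-temperature series for ``year``.

    Each season is its mean plus one full sinusoidal cycle across its days
    (so with zero noise the seasonal sample mean equals the spec mean
    exactly) plus Gaussian day-to-day noise.
    """
    rng = np.random.default_rng(spec.seed)
    calendar = season_dates(year)
    out: dict[str, list[DailyWeather]] = {}
    for season in SEASONS:
        dates = calendar[season]
        n = len(dates)
        phase = np.sin(2.0 * np.pi * np.arange(n) / n)
        noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
        temps = spec.means[season] + spec.amplitudes[season] * phase + noise
        out[season] = [DailyWeather(d, float(t)) for d, t in zip(dates, temps)]
    return out


def fixture_city_spec(seed: int = 0) -> CitySpec:
    """Small (64×64) city used by the test suite and example scripts."""
    return CitySpec(
        n_districts=6,
        total_population=500_000,
        shape=(64, 64),
        cellsize=100.0,
        landuse_refine=4,
        green_fraction=0.25,
        seed=seed,
    )
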