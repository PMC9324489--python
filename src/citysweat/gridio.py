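"""File round-tripping: ESRI ASCII grids, CSV tables, weather series.

Rasters use the plain-text ESRI ASCII grid format (ncols/nrows/xllcorner/
yllcorner/cellsize/NODATA_value header, row-major north-up body), which any
GIS reads and which needs no binary dependencies. Tables go through pandas
CSV.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import DailyWeather
from .thermo import ActivityLevel, ClothingEnsemble
from .upscale import DistrictMap, PopulationRaster

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_population_raster",
    "read_population_raster",
    "write_district_map",
    "read_district_map",
    "write_weather_csv",
    "read_weather_csv",
    "read_activity_table",
    "read_clothing_table",
]


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    cellsize: float,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999.0,
    fmt: str = "%.10g",
) -> None:
    data = np.asarray(data)
    path = Path(path)
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        f"xllcorner {xllcorner:.10g}\n"
        f"yllcorner {yllcorner:.10g}\n"
        f"cellsize {cellsize:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    if "ncols" not in meta or "nrows" not in meta or "cellsize" not in meta:
        raise ValueError(f"{path}: not an ESRI ASCII grid (missing header)")
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    expected = (int(meta["nrows"]), int(meta["ncols"]))
    if data.shape != expected:
        raise ValueError(f"{path}: body shape {data.shape} != header {expected}")
    return data, meta


def write_population_raster(path: str | Path, pop: PopulationRaster) -> None:
    write_ascii_grid(
        path, pop.data, pop.cellsize, pop.xllcorner, pop.yllcorner, pop.nodata
    )


def read_population_raster(path: str | Path) -> PopulationRaster:
    data, meta = read_ascii_grid(path)
    return PopulationRaster(
        data,
        cellsize=meta["cellsize"],
        xllcorner=meta.get("xllcorner", 0.0),
        yllcorner=meta.get("yllcorner", 0.0),
        nodata=meta.get("nodata_value", -9999.0),
    )


def write_district_map(
    grid_path: str | Path, table_path: str | Path, districts: DistrictMap
) -> None:
    write_ascii_grid(grid_path, districts.labels, districts.cellsize, fmt="%d")
    areas = districts.areas_km2()
    pd.DataFrame(
        {
            "label": sorted(districts.names),
            "name": [districts.names[k] for k in sorted(districts.names)],
            "area_km2": [areas.get(k, 0.0) for k in sorted(districts.names)],
        }
    ).to_csv(table_path, index=False)


def read_district_map(grid_path: str | Path, table_path: str | Path) -> DistrictMap:
    data, meta = read_ascii_grid(grid_path)
    table = pd.read_csv(table_path)
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return DistrictMap(data.astype(np.int64), names, cellsize=meta["cellsize"])


def write_weather_csv(path: str | Path, weather: dict[str, list[DailyWeather]]) -> None:
    rows = [
        {"season": season, "date": d.date.isoformat(), "tmean_c": d.tmean}
        for season, days in weather.items()
        for d in days
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> dict[str, list[DailyWeather]]:
    table = pd.read_csv(path)
    out: dict[str, list[DailyWeather]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(row.season, []).append(
            DailyWeather(dt.date.fromisoformat(row.date), float(row.tmean_c))
        )
    return out


def read_activity_table(path: str | Path) -> dict[str, ActivityLevel]:
    """Activity parameters from CSV with columns name,M,hc,fr[,eta]."""
    table = pd.read_csv(path)
    out = {}
    for row in table.itertuples(index=False):
        out[row.name] = ActivityLevel(
            row.name, M=float(row.M), hc=float(row.hc), fr=float(row.fr),
            eta=float(getattr(row, "eta", 0.0)),
        )
    return out


def read_clothing_table(path: str | Path, icl_unit: str = "clo") -> dict[str, ClothingEnsemble]:
    """Clothing parameters from CSV with columns season,fcl,Icl,icl."""
    table = pd.read_csv(path)
    out = {}
    for row in table.itertuples(index=False):
        out[row.season] = ClothingEnsemble(
            row.season, fcl=float(row.fcl), Icl=float(row.Icl),
            icl=float(row.icl), Icl_unit=icl_unit,
        )
    return out
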