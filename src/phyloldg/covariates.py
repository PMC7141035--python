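"""Per-reserve environmental predictors from gridded inputs.

Implements the covariate derivations used by the gradient and importance
stages: topographic roughness TR = 1/cos(slope) from a DEM (Horn slope),
climate indices (MAP, MAT, MTCM) from monthly grids for the current climate
and the Last Glacial Maximum (LGM, ~21 ka BP), the temperature anomaly since
the LGM, NDVI annual means via monthly maximum-value composites, and masked
grid-to-reserve averaging. Rasters are exchanged as ESRI ASCII grids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Per-reserve covariate columns expected by the modeling stages.
RESERVE_COLUMNS = [
    "reserve_id", "lat", "lon",
    "MAP", "PET", "PET2", "MTCM", "NDVI", "AREA", "E_max", "NCT", "TR",
    "GDP", "POP", "LGM_MAP", "LGM_MTCM", "T_Anomaly",
]

#: Predictors entered in the bivariate and multivariate models. AREA is
#: modeled as its natural log (LN_AREA); the remaining columns enter raw.
MODELED_PREDICTORS = [
    "PET", "PET2", "MAP", "NDVI", "LN_AREA", "NCT", "E_max", "TR",
    "GDP", "POP", "MTCM", "LGM_MAP", "LGM_MTCM", "T_Anomaly",
]


@dataclass
class GridLayer:
    """A single raster layer with a validity mask.

    ``values`` holds the raw cell values; cells equal to ``nodata`` (or
    non-finite) are invalid. ``cellsize`` is the square cell edge length and
    (``xll``, ``yll``) the lower-left corner, as in ESRI ASCII headers.
    """

    values: np.ndarray
    nodata: float = -9999.0
    cellsize: float = 1.0
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be 2-D")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)


def read_ascii_grid(path) -> GridLayer:
    """Read an ESRI ASCII grid (.asc). NODATA honored from the header."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "xllcenter", "yllcenter", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: missing ncols/nrows header")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    cs = header.get("cellsize", 1.0)
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cs / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cs / 2)
    return GridLayer(values=values, nodata=header.get("nodata_value", -9999.0),
                     cellsize=cs, xll=xll, yll=yll)


def write_ascii_grid(layer: GridLayer, path) -> None:
    nrows, ncols = layer.values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {layer.xll!r}\n")
        fh.write(f"yllcorner {layer.yll!r}\n")
        fh.write(f"cellsize {layer.cellsize!r}\n")
        fh.write(f"NODATA_value {layer.nodata!r}\n")
        out = np.where(layer.mask, layer.values, layer.nodata)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


@dataclass
class MonthlyClimate:
    """Twelve monthly mean temperatures (degC) and precipitation (mm) for one era."""

    temperature: np.ndarray  # shape (12,) or (12, nr, nc)
    precipitation: np.ndarray
    era: str = "current"  # "current" | "LGM"

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.precipitation = np.asarray(self.precipitation, dtype=float)
        if self.temperature.shape[0] != 12 or self.precipitation.shape[0] != 12:
            raise ValueError("MonthlyClimate requires exactly 12 monthly layers of each")
        if np.any(self.precipitation < 0):
            raise ValueError("precipitation must be nonnegative")
        if self.era not in ("current", "LGM"):
            raise ValueError("era must be 'current' or 'LGM'")


def climate_indices(mc: MonthlyClimate) -> dict[str, np.ndarray | float]:
    """MAP (annual sum of monthly precipitation), MTCM (coldest-month mean
    temperature) and MAT (annual mean temperature); elementwise for grids."""
    return {
        "MAP": np.sum(mc.precipitation, axis=0),
        "MTCM": np.min(mc.temperature, axis=0),
        "MAT": np.mean(mc.temperature, axis=0),
    }


def anomaly(current: MonthlyClimate, lgm: MonthlyClimate) -> np.ndarray | float:
    """Temperature anomaly since the LGM: MAT(current) - MAT(LGM).

    Positive values mean warming since the glacial maximum.
    """
    if current.era == "LGM" or lgm.era == "current":
        raise ValueError("anomaly(current, lgm): era labels look swapped")
    return climate_indices(current)["MAT"] - climate_indices(lgm)["MAT"]


def topographic_roughness(slope_deg):
    """TR = 1/cos(slope), slope in degrees in [0, 90).

    A flat cell has TR = 1; TR grows without bound as slope approaches 90.
    Accepts scalars or arrays.
    """
    slope = np.asarray(slope_deg, dtype=float)
    if np.any(slope < 0) or np.any(slope >= 90):
        raise ValueError("slope must satisfy 0 <= slope < 90 degrees")
    tr = 1.0 / np.cos(np.deg2rad(slope))
    return float(tr) if np.isscalar(slope_deg) else tr


def slope_from_dem(dem: GridLayer) -> GridLayer:
    """Per-cell slope (degrees) from a DEM via Horn's 3x3 kernel.

    Border cells (and no-data neighbors) are handled by nearest-neighbor
    edge replication. Requires at least a 3x3 grid.
    """
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    if dem.cellsize <= 0:
        raise ValueError("cellsize must be positive")
    work = np.where(dem.mask, z, np.nan)
    if not dem.mask.any():
        raise ValueError("DEM has no valid cells")
    # fill no-data from nearby valid cells (iterative neighbor averaging),
    # so Horn differences next to holes behave like edge replication
    while np.isnan(work).any():
        p = np.pad(work, 1, mode="edge")
        nr, nc = work.shape
        neigh = np.stack([p[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
                          for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                          if (dr, dc) != (0, 0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN holes
            fill = np.nanmean(neigh, axis=0)
        work = np.where(np.isnan(work), fill, work)
    p = np.pad(work, 1, mode="edge")
    a = p[:-2, :-2]; b = p[:-2, 1:-1]; c = p[:-2, 2:]
    d = p[1:-1, :-2];                  f = p[1:-1, 2:]
    g = p[2:, :-2];  h = p[2:, 1:-1];  i = p[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dem.cellsize)
    dz_dy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dem.cellsize)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    out = np.where(dem.mask, slope, dem.nodata)
    return GridLayer(values=out, nodata=dem.nodata, cellsize=dem.cellsize,
                     xll=dem.xll, yll=dem.yll)


def ndvi_annual(years: Sequence[Sequence[Sequence[np.ndarray]]],
                mask: np.ndarray | None = None) -> float:
    """Annual NDVI scalar from dekadal layers via maximum-value composites.

    ``years`` is a sequence of years; each year is a sequence of 12 months;
    each month is a sequence of >= 1 dekadal 2-D layers (typically 3, one
    per ~10-day composite). Per cell: the monthly value is the maximum over
    that month's dekads (suppresses cloud contamination), the annual value
    is the mean of the 12 monthly values, and the returned scalar is the
    mean over valid cells and over years.

    A single year may be passed as a bare 12-month sequence.
    """
    if len(years) == 12 and years and isinstance(years[0], (list, tuple)) and (
            len(years[0]) == 0 or isinstance(years[0][0], np.ndarray)):
        years = [years]  # a single year passed directly
    annual_means = []
    for year in years:
        if len(year) != 12:
            raise ValueError(f"each year needs 12 months, got {len(year)}")
        monthly = []
        for m, dekads in enumerate(year, start=1):
            if len(dekads) == 0:
                raise ValueError(f"month {m} has no dekadal layers")
            monthly.append(np.max(np.stack([np.asarray(d, float) for d in dekads]), axis=0))
        annual = np.mean(np.stack(monthly), axis=0)
        if mask is not None:
            if not mask.any():
                raise ValueError("mask excludes every cell")
            annual = annual[mask]
        annual_means.append(float(np.mean(annual)))
    return float(np.mean(annual_means))


def aggregate_reserve(layer: GridLayer) -> float:
    """Arithmetic mean of a layer over its valid cells (no-data excluded)."""
    m = layer.mask
    if not m.any():
        raise ValueError("no valid cells to aggregate")
    return float(layer.values[m].mean())


def thornthwaite_pet(monthly_temp_c: Sequence[float],
                     latitude_deg: float) -> float:
    """Annual potential evapotranspiration (mm) by Thornthwaite's method.

    Convenience helper for building a PET covariate from monthly mean
    temperatures when no PET grid is supplied; any externally supplied PET
    layer takes precedence. Uses mean month lengths and a day-length
    correction from latitude.
    """
    t = np.asarray(monthly_temp_c, dtype=float)
    if t.shape != (12,):
        raise ValueError("need 12 monthly temperatures")
    tpos = np.clip(t, 0.0, None)
    heat_index = float(np.sum((tpos / 5.0) ** 1.514))
    if heat_index == 0:
        return 0.0
    alpha = (6.75e-7 * heat_index ** 3 - 7.71e-5 * heat_index ** 2
             + 1.792e-2 * heat_index + 0.49239)
    days = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    mid_doy = np.cumsum(days) - days / 2
    lat = math.radians(latitude_deg)
    decl = 0.409 * np.sin(2 * math.pi * mid_doy / 365.25 - 1.39)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    daylen = 24.0 / math.pi * np.arccos(cos_h)
    pet_m = 16.0 * (daylen / 12.0) * (days / 30.0) * (10.0 * tpos / heat_index) ** alpha
    return float(np.sum(pet_m))
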