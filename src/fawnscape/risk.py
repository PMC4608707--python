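"""Integrated predation risk, winter severity index, and greenness summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiskSurface",
    "integrate_risk",
    "daily_wsi",
    "annual_wsi",
    "greenness_summary",
]


@dataclass
class RiskSurface:
    """Per-species and integrated (summed) predation risk on the fawn grid."""

    species: dict[str, np.ndarray]
    integrated: np.ndarray

    def at_cells(self, cell_ids: np.ndarray) -> np.ndarray:
        return self.integrated[np.asarray(cell_ids, dtype=int)]


def integrate_risk(surfaces: dict[str, np.ndarray]) -> RiskSurface:
    """Sum the per-species selection surfaces cellwise.

    Each surface is a flat per-cell array in [0, 1] on the shared fawn grid;
    the integrated value therefore lies in [0, n_species].
    """
    names = list(surfaces)
    if not names:
        raise ValueError("no surfaces supplied")
    ref = np.asarray(surfaces[names[0]], dtype=float)
    clean = {}
    for name in names:
        arr = np.asarray(surfaces[name], dtype=float)
        if arr.shape != ref.shape:
            raise ValueError(f"surface extent mismatch: {name}")
        clean[name] = arr
    return RiskSurface(clean, np.sum(list(clean.values()), axis=0))


def daily_wsi(snow_cm, wind_kph, rain_cm, tmin_c) -> np.ndarray:
    """Daily winter severity: (snow + wind + rain) - tmin.

    Severity increases with snow depth, wind speed and rainfall and with
    colder minimum temperature, so colder days (negative tmin) raise the
    index.  Days with any missing component are excluded upstream.
    """
    snow = np.asarray(snow_cm, dtype=float)
    wind = np.asarray(wind_kph, dtype=float)
    rain = np.asarray(rain_cm, dtype=float)
    tmin = np.asarray(tmin_c, dtype=float)
    if np.any(snow < 0) or np.any(wind < 0) or np.any(rain < 0):
        raise ValueError("snow, wind and rain must be nonnegative")
    return (snow + wind + rain) - tmin


def annual_wsi(weather: pd.DataFrame) -> pd.DataFrame:
    """Annual winter severity: per-year sum of daily values, centered across years.

    Input needs columns ``year, snow_cm, wind_kph, rain_cm, tmin_c`` covering
    1 Jan-31 Mar per year.  Rows with missing components are dropped (and
    counted).  Centering subtracts the across-year mean of the annual sums;
    with a single year the raw sum is returned uncentered with a warning.
    """
    w = weather.dropna(subset=["snow_cm", "wind_kph", "rain_cm", "tmin_c"])
    n_dropped = len(weather) - len(w)
    if n_dropped:
        warnings.warn(f"{n_dropped} weather days with missing values excluded",
                      stacklevel=2)
    daily = daily_wsi(w["snow_cm"], w["wind_kph"], w["rain_cm"], w["tmin_c"])
    sums = pd.Series(daily, index=w["year"].to_numpy()).groupby(level=0).sum()
    out = pd.DataFrame({"year": sums.index, "raw_sum": sums.to_numpy()})
    if len(out) < 2:
        warnings.warn("fewer than 2 years: centering skipped", stacklevel=2)
        out["centered"] = out["raw_sum"]
    else:
        out["centered"] = out["raw_sum"] - out["raw_sum"].mean()
    return out.reset_index(drop=True)


def greenness_summary(pixels: np.ndarray, year: int) -> pd.DataFrame:
    """Mean and SD of greenness (NDVI-like) pixel values over the study area."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    pixels = pixels[np.isfinite(pixels)]
    if pixels.size == 0:
        raise ValueError("empty greenness clip")
    return pd.DataFrame(
        {"year": [year], "mean": [pixels.mean()],
         "sd": [pixels.std(ddof=1) if pixels.size > 1 else 0.0],
         "n": [pixels.size]}
    )
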