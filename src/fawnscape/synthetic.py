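"""Synthetic study-system generator.

Emulates the data a landscape-scale neonate-survival field study produces:
a patchy categorical vegetation landscape crossed by roads and permanent
water, four smoothed predator selection surfaces, a daily winter weather
series, fawn cohorts whose birth mass is depressed by winter severity,
telemetry drawn proportional to an exponential resource-selection score with
per-animal random intercepts, and fates drawn from a daily discrete-hazard
proportional-hazards model with shared Gaussian frailty.

Every generator takes an explicit integer seed and is byte-reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .landscape import CategoricalRaster, LandscapeGrid

__all__ = [
    "SyntheticTruth",
    "SyntheticDataset",
    "gen_landscape",
    "gen_predator_surfaces",
    "gen_weather",
    "gen_cohort",
    "gen_telemetry",
    "gen_fates",
]

#: Post-partum season: parturition onset (14 May) to season end (31 Aug),
#: day-of-year on a non-leap calendar.
SEASON_START_DOY = 134
SEASON_END_DOY = 243
PEAK_PARTURITION_DOY = 152  # 1 Jun

WEATHER_LEVELS = ("mild", "moderate", "severe")


@dataclass
class SyntheticTruth:
    """Generative parameters shared across the synthetic pipeline.

    ``rsf_beta`` are selection coefficients on the standardized covariate
    scale; ``hazard_beta`` are log-hazard coefficients for (resource-use
    score, integrated predation risk, birth mass, winter severity,
    mass x winter-severity).  Frailty variances are for Gaussian random
    intercepts on the log hazard shared within fawn and within year.
    """

    rsf_beta: dict[str, float]
    hazard_beta: dict[str, float]
    frailty_var_fawn: float = 0.2
    frailty_var_year: float = 0.1
    mass_intercept_kg: float = 4.1   # cohort mean after an average winter
    mass_slope_kg_per_wsi: float = -0.0025
    mass_sd_kg: float = 0.9
    baseline_hazard: float = 0.008   # per-day; keeps discretization bias small
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frailty_var_fawn < 0 or self.frailty_var_year < 0:
            raise ValueError("frailty variances must be nonnegative")
        if self.mass_sd_kg <= 0:
            raise ValueError("mass sd must be positive")
        for name, vec in (("rsf_beta", self.rsf_beta), ("hazard_beta", self.hazard_beta)):
            if not all(np.isfinite(list(vec.values()))):
                raise ValueError(f"{name} must be finite")


@dataclass
class SyntheticDataset:
    """One fully generated study system (landscape + animals + fates)."""

    raster: CategoricalRaster
    roads: list[LineString]
    water: list[LineString]
    predator_surfaces: dict[str, np.ndarray]  # per-species values on the grid
    weather: pd.DataFrame                      # year, date, snow_cm, wind_kph, rain_cm, tmin_c
    fawns: pd.DataFrame                        # fawn_id, year, birth_doy, birth_mass_kg
    telemetry: pd.DataFrame                    # fawn_id, year, doy, x, y
    fates: pd.DataFrame                        # fawn_id, year, fate_doy, event
    truth: SyntheticTruth
    grid: LandscapeGrid | None = field(default=None, repr=False)
    greenness: dict[int, np.ndarray] = field(default_factory=dict, repr=False)


def gen_landscape(
    seed: int,
    n_rows: int = 100,
    n_cols: int = 100,
    class_weights: np.ndarray | None = None,
    pixel_size: float = 30.0,
    seeds_per_unit_weight: int = 40,
    n_roads: int = 2,
    n_water: int = 2,
) -> tuple[CategoricalRaster, list[LineString], list[LineString]]:
    """Generate a patchy categorical landscape by seeded multi-class region growth.

    Seed pixels are scattered with multiplicity proportional to
    ``class_weights`` and grown simultaneously with randomized accretion
    costs (an Eden-type growth), which yields irregular, spatially clustered
    patches whose expected class shares match the weights.  At least one road
    and one water polyline cross the full extent.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("zero-area extent")
    if class_weights is None:
        class_weights = np.full(8, 1 / 8)
    class_weights = np.asarray(class_weights, dtype=float)
    if len(class_weights) != 8 or np.any(class_weights < 0):
        raise ValueError("class_weights must be 8 nonnegative entries")
    if not np.isclose(class_weights.sum(), 1.0):
        raise ValueError("class_weights must sum to 1")

    rng = np.random.default_rng(seed)
    n_seeds = np.zeros(8, dtype=int)
    pos = class_weights > 0
    n_seeds[pos] = np.maximum(1, np.round(class_weights[pos] * seeds_per_unit_weight)).astype(int)

    values = np.zeros((n_rows, n_cols), dtype=np.int32)
    heap: list[tuple[float, int, int, int]] = []
    total = int(n_seeds.sum())
    cells = rng.choice(n_rows * n_cols, size=total, replace=False)
    k = 0
    for cls in range(8):
        for _ in range(n_seeds[cls]):
            r, c = divmod(int(cells[k]), n_cols)
            k += 1
            heapq.heappush(heap, (rng.exponential(), r, c, cls + 1))
    while heap:
        cost, r, c, cls = heapq.heappop(heap)
        if values[r, c] != 0:
            continue
        values[r, c] = cls
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and values[rr, cc] == 0:
                heapq.heappush(heap, (cost + rng.exponential(), rr, cc, cls))

    raster = CategoricalRaster(values, (0.0, 0.0), pixel_size)
    width = n_cols * pixel_size
    height = n_rows * pixel_size
    roads = [_wavy_line(rng, width, height, horizontal=True) for _ in range(max(1, n_roads))]
    water = [_wavy_line(rng, width, height, horizontal=False) for _ in range(max(1, n_water))]
    return raster, roads, water


def _wavy_line(rng: np.random.Generator, width: float, height: float, horizontal: bool) -> LineString:
    """Polyline crossing the full extent with a bounded random-walk offset."""
    n = 20
    along = np.linspace(0.0, width if horizontal else height, n)
    span = height if horizontal else width
    offset = span * (0.15 + 0.7 * rng.uniform())
    walk = np.cumsum(rng.normal(0, span * 0.02, n))
    across = np.clip(offset + walk - walk.mean(), 0.02 * span, 0.98 * span)
    pts = np.column_stack([along, across] if horizontal else [across, along])
    return LineString(pts)


def gen_predator_surfaces(
    seed: int,
    grid: LandscapeGrid,
    species: tuple[str, ...] = ("bobcat", "black_bear", "coyote", "wolf"),
    smooth_cells: float = 6.0,
) -> dict[str, np.ndarray]:
    """Four smooth predator selection surfaces in [0, 1] on the fawn grid.

    Each is Gaussian-smoothed white noise passed through a logistic squash;
    these stand in for externally estimated predator resource-selection maps.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i, sp in enumerate(species):
        z = rng.normal(size=(grid.n_rows, grid.n_cols))
        z = ndimage.gaussian_filter(z, smooth_cells, mode="reflect")
        z = (z - z.mean()) / (z.std() + 1e-12)
        out[sp] = (1.0 / (1.0 + np.exp(-1.5 * z))).ravel()
    return out


#: Weather level parameters: (snow mean cm, tmin mean C).  Chosen so annual
#: index sums spread by a few hundred units between mild and severe winters.
_WEATHER_PARAMS = {"mild": (1.0, -0.5), "moderate": (3.5, -2.5), "severe": (6.5, -5.5)}


def gen_weather(
    seed: int,
    severity_level: str,
    year: int = 2009,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Daily winter weather series, 1 Jan-31 Mar (90 days, non-leap calendar).

    Severe winters have deeper snow and colder minimum temperatures than mild
    ones, so the annual severity index is ordered severe > moderate > mild.
    With ``noise_sd=0`` the series is deterministic (smooth seasonal shape).
    """
    if severity_level not in _WEATHER_PARAMS:
        raise ValueError(f"severity_level must be one of {WEATHER_LEVELS}")
    rng = np.random.default_rng(seed)
    snow_mu, tmin_mu = _WEATHER_PARAMS[severity_level]
    doy = np.arange(1, 91)
    season = np.cos((doy - 30) / 90 * np.pi)  # peaks late January, relaxes to spring
    snow = np.maximum(0.0, snow_mu * (0.6 + 0.6 * season) + rng.normal(0, 1.5 * noise_sd, 90))
    wind = np.maximum(0.0, 10.0 + rng.normal(0, 3 * noise_sd, 90))
    rain = np.maximum(0.0, rng.normal(0.05, 0.2 * noise_sd, 90))
    tmin = tmin_mu * (0.5 + 0.8 * season) + rng.normal(0, 2 * noise_sd, 90)
    return pd.DataFrame(
        {"year": year, "doy": doy, "snow_cm": snow, "wind_kph": wind,
         "rain_cm": rain, "tmin_c": tmin}
    )


def gen_cohort(
    seed: int,
    n_fawns: int,
    annual_wsi: float,
    year: int = 2009,
    mass_intercept_kg: float = 4.1,
    mass_slope_kg_per_wsi: float = -0.0025,
    mass_sd_kg: float = 0.9,
    birth_doy_sd: float = 10.0,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Fawn cohort for one year: ids, birth dates, birth masses.

    Birth mass ~ Normal(intercept + slope * WSI, sd), truncated above 0.5 kg
    (redrawn); birth dates cluster around peak parturition (1 Jun) and are
    clipped to the capture season.
    """
    if n_fawns < 1:
        raise ValueError("n_fawns must be >= 1")
    if mass_sd_kg <= 0:
        raise ValueError("mass sd must be positive")
    rng = np.random.default_rng(seed)
    mu = mass_intercept_kg + mass_slope_kg_per_wsi * annual_wsi
    mass = rng.normal(mu, mass_sd_kg, n_fawns)
    while np.any(mass <= 0.5):
        bad = mass <= 0.5
        mass[bad] = rng.normal(mu, mass_sd_kg, bad.sum())
    birth = np.clip(
        np.round(rng.normal(PEAK_PARTURITION_DOY, birth_doy_sd, n_fawns)),
        SEASON_START_DOY,
        SEASON_END_DOY - 10,
    ).astype(int)
    return pd.DataFrame(
        {
            "fawn_id": id_offset + np.arange(n_fawns),
            "year": year,
            "birth_doy": birth,
            "birth_mass_kg": mass,
        }
    )


def gen_telemetry(
    seed: int,
    fawn_id: int,
    year: int,
    birth_doy: int,
    grid: LandscapeGrid,
    covariates: np.ndarray,
    rsf_beta: np.ndarray,
    n_locs: int,
    fawn_intercept: float = 0.0,
    end_doy: int = SEASON_END_DOY,
) -> pd.DataFrame:
    """Telemetry points for one fawn, drawn cell-wise from the selection score.

    Cells are sampled with probability proportional to
    ``exp(covariates @ rsf_beta + fawn_intercept)`` and positions jittered
    uniformly within the cell (the positional-error model the 2115 m^2 cell
    encodes).  Dates are sorted random days in (birth, end of season].
    """
    covariates = np.asarray(covariates, dtype=float)
    score = covariates @ np.asarray(rsf_beta, dtype=float) + fawn_intercept
    score = np.exp(score - score.max())
    tot = score.sum()
    if not np.isfinite(tot) or tot <= 0:
        raise ValueError("all-cell selection score is zero")
    rng = np.random.default_rng(seed)
    cells = rng.choice(grid.n_cells, size=n_locs, p=score / tot)
    rows, cols = np.divmod(cells, grid.n_cols)
    x = grid.origin[0] + (cols + rng.uniform(0, 1, n_locs)) * grid.cell_side
    y = grid.origin[1] + (rows + rng.uniform(0, 1, n_locs)) * grid.cell_side
    days = np.sort(rng.choice(np.arange(birth_doy + 1, end_doy + 1),
                              size=min(n_locs, end_doy - birth_doy), replace=False))
    if len(days) < n_locs:  # very late births: allow repeated days
        days = np.sort(rng.integers(birth_doy + 1, end_doy + 1, n_locs))
    return pd.DataFrame(
        {"fawn_id": fawn_id, "year": year, "doy": days[:n_locs], "x": x, "y": y}
    )


def gen_fates(
    seed: int,
    fawns: pd.DataFrame,
    daily_covariates: dict[int, np.ndarray] | None,
    hazard_beta: np.ndarray,
    frailty_var_fawn: float = 0.0,
    frailty_var_year: float = 0.0,
    baseline_hazard: float = 0.008,
    end_doy: int = SEASON_END_DOY,
) -> pd.DataFrame:
    """Draw a fate (death day or censoring) per fawn from a daily hazard model.

    The day-by-day death probability is ``h0 * exp(x beta + b_fawn + b_year)``
    (a discrete approximation to the continuous proportional-hazards model;
    with h <= 0.05/day the discretization bias is small).  ``daily_covariates``
    maps fawn_id to an (n_days, k) array covering birth+1 .. end_doy; pass
    None for a covariate-free model.  Fawns alive past 31 Aug are censored.
    """
    if np.any(np.atleast_1d(baseline_hazard) < 0):
        raise ValueError("baseline_hazard must be nonnegative per day")
    if frailty_var_fawn < 0 or frailty_var_year < 0:
        raise ValueError("frailty variances must be nonnegative")
    rng = np.random.default_rng(seed)
    hazard_beta = np.asarray(hazard_beta, dtype=float)
    years = np.sort(fawns["year"].unique())
    b_year = {y: rng.normal(0, np.sqrt(frailty_var_year)) for y in years}

    recs = []
    for rec in fawns.itertuples(index=False):
        b = rng.normal(0, np.sqrt(frailty_var_fawn)) + b_year[rec.year]
        days = np.arange(rec.birth_doy + 1, end_doy + 1)
        if daily_covariates is None:
            eta = np.zeros(len(days))
        else:
            X = np.asarray(daily_covariates[rec.fawn_id], dtype=float)
            eta = X[: len(days)] @ hazard_beta
        p = np.clip(baseline_hazard * np.exp(eta + b), 0.0, 0.95)
        u = rng.uniform(size=len(days))
        hit = np.nonzero(u < p)[0]
        if len(hit):
            recs.append((rec.fawn_id, rec.year, int(days[hit[0]]), 1))
        else:
            recs.append((rec.fawn_id, rec.year, end_doy, 0))
    return pd.DataFrame(recs, columns=["fawn_id", "year", "fate_doy", "event"])
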