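"""Spatially predictive mortality: extrapolate the fitted daily-survival
model across the analysis grid.

Per year j and cell with (standardized) covariates x, the cumulative
survival to season end is S_j(t_e | x) = S0_j(t_e) ** exp(x' beta), with
S0_j the Breslow baseline cumulative survival of year j.  The mapped
quantity is mortality 1 - S, linear-stretched to [0, 1] over the grid
(higher values = relatively greater mortality likelihood).  Only covariates
that vary over space (the resource-use score and integrated predation risk)
enter x; cell-constant covariates (birth mass, winter severity) sit at their
sample means, i.e. 0 on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxfrailty import CoxFrailtyFit, breslow_baseline
from .landscape import LandscapeGrid
from .rsf import linear_stretch

__all__ = [
    "MortalitySurface",
    "baseline_cumulative_survival",
    "predict_cell_survival",
    "mortality_map",
]


@dataclass
class MortalitySurface:
    """Per-cell, per-year survival and stretched relative mortality."""

    grid: LandscapeGrid
    table: pd.DataFrame  # cell_id, year, linear_predictor, S, mortality, stretched

    def per_year(self, year) -> pd.DataFrame:
        return self.table[self.table["year"] == year]


def baseline_cumulative_survival(
    fit: CoxFrailtyFit,
    intervals: pd.DataFrame,
    year,
    t_end: float | None = None,
    include_frailty: bool = True,
) -> float:
    """Breslow baseline cumulative survival S0_j(t_e) for one year.

    With no events in the year the baseline survival is 1.  ``t_end``
    defaults to the last observed stop time of the year.
    """
    if year not in set(intervals["year"]):
        raise ValueError(f"year {year} absent from intervals")
    bl = breslow_baseline(fit, intervals, include_frailty=include_frailty)
    bl = bl[bl["year"] == year]
    if t_end is None:
        t_end = float(intervals.loc[intervals["year"] == year, "stop"].max())
    bl = bl[bl["time"] <= t_end]
    if len(bl) == 0:
        return 1.0
    return float(bl["S0"].iloc[-1])


def predict_cell_survival(
    s0: float, linear_predictor: np.ndarray
) -> np.ndarray:
    """S = S0 ** exp(x'beta), elementwise over cells."""
    if not (0.0 < s0 <= 1.0):
        raise ValueError("baseline survival must lie in (0, 1]")
    return s0 ** np.exp(np.asarray(linear_predictor, dtype=float))


def mortality_map(
    fit: CoxFrailtyFit,
    intervals: pd.DataFrame,
    grid: LandscapeGrid,
    cell_covariates: pd.DataFrame,
    years: list | None = None,
    include_frailty: bool = True,
) -> MortalitySurface:
    """Per-cell relative mortality probability, stretched to [0, 1] per year set.

    ``cell_covariates`` holds the spatially varying covariates on the fitted
    standardized scale (one row per cell); model covariates absent from it
    are held at 0.  Mortality 1 - S is stretched jointly over all mapped
    cells and years so the most dangerous cell attains exactly 1.
    """
    if years is None:
        years = sorted(set(intervals["year"]))
    eta = np.zeros(len(cell_covariates))
    for c, b in zip(fit.covariates, fit.coef):
        if c in cell_covariates.columns:
            eta = eta + b * cell_covariates[c].to_numpy(dtype=float)
    recs = []
    for year in years:
        s0 = baseline_cumulative_survival(fit, intervals, year,
                                          include_frailty=include_frailty)
        S = predict_cell_survival(s0, eta)
        recs.append(pd.DataFrame({
            "cell_id": np.arange(len(cell_covariates)),
            "year": year,
            "linear_predictor": eta,
            "S": S,
            "mortality": 1.0 - S,
        }))
    table = pd.concat(recs, ignore_index=True)
    table["stretched"] = linear_stretch(table["mortality"].to_numpy())
    return MortalitySurface(grid, table)
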