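"""Use-availability resource selection functions and suitability mapping.

Second-order selection: used telemetry points (1) are contrasted against
random availability points (0) drawn from the pooled minimum convex polygon,
with a binomial GLMM (random intercepts for fawn and year).  Fitted
standardized coefficients score every grid cell through the exponential
selection function w(x) = exp(b0 + b1 x1 + ... + bk xk), and a linear
stretch maps the scores to [0, 1] suitability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMFit, fit_logistic_glmm
from .landscape import LandscapeGrid, Standardizer

__all__ = [
    "RSFModelFit",
    "SuitabilitySurface",
    "fit_use_availability",
    "evaluate_model_set",
    "auc",
    "suitability_score",
    "linear_stretch",
]


@dataclass
class RSFModelFit:
    """One use-availability model: coefficients, variances, likelihood, AUC."""

    label: str
    covariates: list[str]
    fit: GLMMFit
    auc: float

    @property
    def n_parameters(self) -> int:
        return len(self.fit.coef) + len(self.fit.variances)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.fit.coef_names,
                "coefficient": self.fit.coef,
                "se": self.fit.se,
                "z": self.fit.zvalues,
                "p": self.fit.pvalues,
            }
        )


@dataclass
class SuitabilitySurface:
    """Raw exponential scores and [0,1]-stretched suitability per grid cell."""

    grid: LandscapeGrid
    raw: np.ndarray
    stretched: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.stretched = linear_stretch(self.raw)

    def at_cells(self, cell_ids) -> np.ndarray:
        return self.stretched[np.asarray(cell_ids, dtype=int)]


def _design(table: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in covariates]
    )
    return X, ["(intercept)", *covariates]


def fit_use_availability(
    table: pd.DataFrame,
    covariates: list[str],
    random: tuple[str, ...] = ("fawn_id", "year"),
    response: str = "used",
    label: str | None = None,
    variances: dict[str, float] | None = None,
) -> RSFModelFit:
    """Fit one binomial use-availability mixed model by Laplace ML.

    ``table`` must carry the 0/1 response, standardized covariate columns and
    the grouping columns.  AUC is computed on the population-level fitted
    linear predictor (fixed effects only): random-intercept modes would let
    a covariate-free model memorize per-group class balance, so with them a
    null model would not score 0.5.
    """
    y = table[response].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("response must contain both used (1) and available (0) rows")
    X, names = _design(table, covariates)
    codes = {
        g: pd.factorize(table[g])[0] for g in random
    }
    fit = fit_logistic_glmm(y, X, codes, names, variances=variances)
    big = [nm for nm, c in zip(names[1:], fit.coef[1:]) if abs(c) > 15]
    if big:
        warnings.warn(f"possible separation: covariate(s) {big} have extreme "
                      "coefficients", stacklevel=2)
    scores = fit.linear_predictor(X)
    return RSFModelFit(label or " + ".join(covariates) or "null",
                       list(covariates), fit, auc(scores, y))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Ties receive half credit, so identical scores give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_model_set(
    table: pd.DataFrame,
    candidates: list[str],
    random: tuple[str, ...] = ("fawn_id", "year"),
    alpha: float = 0.05,
    extra_models: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Null, univariate, and additive-of-significant models, ranked by AUC.

    Follows the two-stage screen: every candidate is first fitted alone; the
    individually significant ones (Wald p < alpha) enter a global additive
    model.  Extra additive models may be supplied by name.  Ties in AUC are
    broken in favour of fewer parameters.  Models that fail to fit are
    recorded with their error and excluded from the ranking.
    """
    fits: list[RSFModelFit] = []
    errors: list[tuple[str, str]] = []

    def try_fit(label, covs):
        try:
            fits.append(fit_use_availability(table, covs, random, label=label))
        except Exception as exc:  # noqa: BLE001 - suite continues past bad models
            errors.append((label, str(exc)))

    try_fit("null", [])
    significant = []
    for c in candidates:
        try_fit(c, [c])
        last = fits[-1]
        if last.label == c and last.fit.pvalues[1] < alpha:
            significant.append(c)
    if len(significant) > 1:
        try_fit("global", significant)
    for label, covs in (extra_models or {}).items():
        try_fit(label, covs)

    rows = []
    for f in fits:
        rows.append({
            "model": f.label,
            "k": f.n_parameters,
            "auc": f.auc,
            "loglik": f.fit.loglik,
            "fit": f,
        })
    out = pd.DataFrame(rows).sort_values(
        ["auc", "k"], ascending=[False, True]
    ).reset_index(drop=True)
    out.attrs["errors"] = errors
    out.attrs["significant"] = significant
    return out


def suitability_score(
    grid_covariates: pd.DataFrame,
    fit: RSFModelFit,
    grid: LandscapeGrid,
    standardizer: Standardizer | None = None,
) -> SuitabilitySurface:
    """Exponential selection score per cell: w = exp(b0 + x'b).

    ``grid_covariates`` must contain the model's covariates; if a
    ``standardizer`` (fitted on the use-availability sample) is given the
    raw cell values are z-scored with the *sample* means/SDs first, so the
    scores live on the fitted scale.
    """
    cov = grid_covariates
    if standardizer is not None:
        cov = standardizer.transform(cov)
    for c in fit.covariates:
        if c not in cov.columns:
            raise KeyError(f"covariate missing from grid: {c}")
    eta = np.full(len(cov), fit.fit.coef[0])
    n_missing = 0
    for c, b in zip(fit.covariates, fit.fit.coef[1:]):
        x = cov[c].to_numpy(dtype=float)
        miss = ~np.isfinite(x)
        if miss.any():
            # undefined metrics (e.g. no other same-class patch) sit at the
            # sample mean, which is 0 on the standardized scale
            x = np.where(miss, 0.0, x)
            n_missing += int(miss.sum())

        eta = eta + b * x
    if n_missing:
        warnings.warn(f"{n_missing} missing covariate values scored at the "
                      "sample mean", stacklevel=2)
    w = np.exp(eta)
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("non-finite suitability score")
    return SuitabilitySurface(grid, w)


def linear_stretch(values: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]: (w - wmin) / (wmax - wmin).

    The minimum maps to exactly 0 and the maximum to exactly 1; order is
    preserved.  A constant input has no range, so every value maps to 0.5
    (with a warning).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        warnings.warn("constant surface: linear stretch returns 0.5 everywhere",
                      stacklevel=2)
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)
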