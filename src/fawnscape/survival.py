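"""Survival analysis: counting-process intervals, Kaplan-Meier with staggered
entry, the k-sample log-rank test, and the mixed-effects Cox model suites.

Time is measured in calendar days (day of year), with each fawn entering the
risk set at its birth date (delayed entry) and leaving at death or censoring
(31 Aug).  Daily models carry the covariates of the opening relocation across
each inter-relocation interval; seasonal models collapse each fawn to a
single interval with season-averaged covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .coxfrailty import CoxFrailtyFit, fit_cox_frailty

__all__ = [
    "KMCurve",
    "build_intervals",
    "km_fit",
    "logrank",
    "deviance_explained",
    "SUITE_MODELS",
    "run_suite",
]


def build_intervals(
    fawns: pd.DataFrame,
    fates: pd.DataFrame,
    telemetry: pd.DataFrame,
    covariate_cols: list[str],
    mode: str = "daily",
    seasonal_stat: str = "mean",
) -> pd.DataFrame:
    """Assemble counting-process survival intervals.

    daily mode: one row per inter-relocation gap ``(t_k, t_{k+1}]`` carrying
    the covariates recorded at the opening relocation; the final interval
    closes at the fate (death or censor) date and carries the event flag.
    seasonal mode: one row per fawn spanning birth to fate with covariates
    averaged (mean, or median via ``seasonal_stat``) over its relocations.

    ``telemetry`` must have columns fawn_id, doy and the covariate columns
    (already extracted at each relocation).  Relocations dated after the fate
    are rejected and counted in ``result.attrs['n_rejected']``.
    """
    if mode not in ("daily", "seasonal"):
        raise ValueError("mode must be 'daily' or 'seasonal'")
    fate_map = fates.set_index("fawn_id")[["fate_doy", "event"]]
    merged = fawns.merge(fate_map, on="fawn_id")

    rows = []
    n_rejected = 0
    tel_groups = dict(tuple(telemetry.groupby("fawn_id")))
    for rec in merged.itertuples(index=False):
        tel = tel_groups.get(rec.fawn_id)
        if tel is None or len(tel) == 0:
            continue  # fawns with no usable relocations drop out
        tel = tel.sort_values("doy")
        late = tel["doy"] > rec.fate_doy
        n_rejected += int(late.sum())
        tel = tel[~late]
        if len(tel) == 0:
            continue
        base = {"fawn_id": rec.fawn_id, "year": rec.year,
                "birth_mass_kg": getattr(rec, "birth_mass_kg", np.nan)}
        if mode == "seasonal":
            stat = tel[covariate_cols].mean() if seasonal_stat == "mean" else tel[covariate_cols].median()
            row = dict(base, start=float(rec.birth_doy), stop=float(rec.fate_doy),
                       event=int(rec.event), **stat.to_dict())
            rows.append(row)
        else:
            tel = tel.drop_duplicates(subset="doy", keep="first")
            reloc = tel["doy"].to_numpy(dtype=float)
            covs = tel[covariate_cols].to_numpy()
            # interval boundaries: birth, each relocation, then the fate date;
            # interval (t_k, t_{k+1}] carries the covariates of its opening
            # relocation (the first pre-relocation interval uses the first fix)
            bounds = np.concatenate([[float(rec.birth_doy)], reloc])
            if bounds[-1] < rec.fate_doy:
                bounds = np.append(bounds, float(rec.fate_doy))
            first = len(rows)
            for k in range(len(bounds) - 1):
                t0, t1 = bounds[k], bounds[k + 1]
                if t1 <= t0:
                    continue
                cov = covs[max(0, min(k - 1, len(covs) - 1))]
                rows.append(dict(base, start=t0, stop=t1, event=0,
                                 **{c: v for c, v in zip(covariate_cols, cov)}))
            if len(rows) > first:
                rows[-1]["event"] = int(rec.event)
    out = pd.DataFrame(rows)
    out.attrs["n_rejected"] = n_rejected
    return out


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood standard errors."""

    group: object
    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> tuple[float, float]:
        """(survival, SE) at time t (step function, right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0, 0.0
        return float(self.survival[idx]), float(self.se[idx])


def _km_one(start, stop, event, group=None) -> KMCurve:
    times = np.unique(stop[event == 1])
    surv, sevar = [], []
    s = 1.0
    gw = 0.0
    n_risk, n_ev = [], []
    for t in times:
        at_risk = int(((start < t) & (t <= stop)).sum())
        d = int(((stop == t) & (event == 1)).sum())
        n_risk.append(at_risk)
        n_ev.append(d)
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        surv.append(s)
        sevar.append(s**2 * gw)
    return KMCurve(group, times, np.asarray(surv), np.sqrt(sevar),
                   np.asarray(n_risk), np.asarray(n_ev))


def km_fit(intervals: pd.DataFrame, by: str | None = None) -> dict:
    """Kaplan-Meier with delayed entry, per group (e.g. per year).

    Subjects enter the risk set at their interval start (birth date); the
    product-limit estimator and Greenwood variance are computed over the
    event times.  Groups with no risk time are skipped with a warning.
    """
    curves = {}
    grouped = [(None, intervals)] if by is None else intervals.groupby(by)
    for g, sub in grouped:
        if len(sub) == 0 or (sub["stop"] - sub["start"]).sum() <= 0:
            warnings.warn(f"group {g} has no risk time; skipped", stacklevel=2)
            continue
        curves[g] = _km_one(
            sub["start"].to_numpy(dtype=float),
            sub["stop"].to_numpy(dtype=float),
            sub["event"].to_numpy(dtype=int),
            group=g,
        )
    return curves


def logrank(intervals: pd.DataFrame, by: str = "year") -> dict:
    """k-sample log-rank test with delayed entry.

    At each event time the observed deaths per group are compared to the
    hypergeometric expectation given the shared risk set; the statistic is
    the quadratic form of (O - E) in the inverse summed covariance with
    df = k - 1.  Returns ``{"chi2", "df", "p"}``.
    """
    groups = np.asarray(pd.factorize(intervals[by])[0])
    k = groups.max() + 1
    if k < 2:
        raise ValueError("need at least 2 groups")
    start = intervals["start"].to_numpy(dtype=float)
    stop = intervals["stop"].to_numpy(dtype=float)
    event = intervals["event"].to_numpy(dtype=int)
    times = np.unique(stop[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in times:
        at_risk = (start < t) & (t <= stop)
        n = at_risk.sum()
        d = int(((stop == t) & (event == 1)).sum())
        if n == 0 or d == 0:
            continue
        ng = np.bincount(groups[at_risk], minlength=k).astype(float)
        dg = np.bincount(groups[(stop == t) & (event == 1)], minlength=k).astype(float)
        O += dg
        E += d * ng / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            V += c * (np.diag(ng / n) - np.outer(ng, ng) / n**2)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = 0.0
    df = k - 1
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df)),
            "observed": O, "expected": E}


def deviance_explained(fit: CoxFrailtyFit, null_loglik: float | None = None) -> dict:
    """Model-ranking statistic: integrated loglik minus the fixed-null loglik.

    The reference is the covariate-free, frailty-free model on the same data,
    so the null model *with* random effects itself explains deviance.
    chi-square = 2 x the difference, with df = parameters added (fixed
    coefficients + frailty variances).
    """
    l0 = fit.null_loglik if null_loglik is None else null_loglik
    dev = fit.loglik - l0
    chi2 = 2.0 * dev
    df = fit.n_parameters
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"deviance_explained": dev, "chi2": chi2, "df": df, "p": p}


def _interactions(terms: list) -> tuple[list[str], list[tuple[str, str]]]:
    mains = [t for t in terms if isinstance(t, str)]
    inters = [t for t in terms if isinstance(t, tuple)]
    return mains, inters


#: The candidate hypotheses for both the daily and the seasonal suites.
#: Terms are standardized covariate columns; tuples denote interactions.
SUITE_MODELS: dict[str, list] = {
    "null": [],
    "resource_use": ["resource_use"],
    "predation_risk": ["predation_risk"],
    "birth_mass": ["birth_mass"],
    "winter_severity": ["winter_severity"],
    "hiding_cover": ["hiding_cover"],
    "maternal_effects": ["birth_mass", "winter_severity",
                         ("birth_mass", "winter_severity")],
    "non_ideal_use": ["resource_use", "predation_risk"],
    "ecological_trap": ["resource_use", "predation_risk",
                        ("resource_use", "predation_risk")],
    "weather_mediated_predation": ["predation_risk", "winter_severity",
                                   ("predation_risk", "winter_severity")],
    "resource_use + maternal_effects": [
        "resource_use", "birth_mass", "winter_severity",
        ("birth_mass", "winter_severity")],
    "predation_risk + maternal_effects": [
        "predation_risk", "birth_mass", "winter_severity",
        ("birth_mass", "winter_severity")],
    "non_ideal_use + maternal_effects": [
        "resource_use", "predation_risk", "birth_mass", "winter_severity",
        ("birth_mass", "winter_severity")],
    "ecological_trap + maternal_effects": [
        "resource_use", "predation_risk", ("resource_use", "predation_risk"),
        "birth_mass", "winter_severity", ("birth_mass", "winter_severity")],
    "weather_mediated_ecological_trap + maternal_effects": [
        "resource_use", "predation_risk", ("resource_use", "predation_risk"),
        "birth_mass", "winter_severity", ("birth_mass", "winter_severity"),
        ("predation_risk", "winter_severity")],
    "non_ideal_use + hiding_cover": ["resource_use", "predation_risk",
                                     "hiding_cover"],
    "ecological_trap + hiding_cover": [
        "resource_use", "predation_risk", ("resource_use", "predation_risk"),
        "hiding_cover"],
}


def add_interaction_columns(intervals: pd.DataFrame,
                            models: dict[str, list] | None = None) -> pd.DataFrame:
    """Product columns 'a:b' for every interaction a model set references."""
    models = SUITE_MODELS if models is None else models
    data = intervals.copy()
    needed = set()
    for terms in models.values():
        needed.update(_interactions(terms)[1])
    for a, b in sorted(needed):
        col = f"{a}:{b}"
        if col not in data.columns:
            data[col] = data[a] * data[b]
    return data


def run_suite(
    intervals: pd.DataFrame,
    models: dict[str, list] | None = None,
    random: tuple[str, ...] = ("fawn_id", "year"),
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every candidate Cox frailty model and rank by deviance explained.

    Interaction columns are built as products of the (standardized) main
    effect columns.  Individual model failures are recorded in
    ``result.attrs['errors']`` and the suite continues.  The returned frame
    has one row per model with its ranking statistics; fitted objects are in
    the ``fit`` column.
    """
    models = SUITE_MODELS if models is None else models
    data = add_interaction_columns(intervals, models)

    rows, errors = [], []
    for name, terms in models.items():
        mains, inters = _interactions(terms)
        cols = mains + [f"{a}:{b}" for a, b in inters]
        try:
            fit = fit_cox_frailty(data, cols, random=random, label=name, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - suite continues past bad models
            errors.append((name, str(exc)))
            continue
        dev = deviance_explained(fit)
        rows.append({
            "model": name,
            "k": fit.n_parameters,
            "deviance_explained": dev["deviance_explained"],
            "loglik_chi2": dev["chi2"],
            "model_p": dev["p"],
            "loglik": fit.loglik,
            "fit": fit,
        })
    out = pd.DataFrame(rows).sort_values(
        "deviance_explained", ascending=False
    ).reset_index(drop=True)
    out.attrs["errors"] = errors
    return out
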