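"""Cox proportional hazards with Gaussian frailty (mixed-effects Cox).

Counting-process intervals (start, stop, event] with delayed entry carry
time-varying covariates; Gaussian random intercepts on the log hazard are
shared within fawn and within year.  For fixed frailty variances the
penalized partial likelihood

    pl(beta, b) - 1/2 sum_f b_f' b_f / theta_f

is maximized jointly by Newton iterations with step-halving (the penalized
likelihood is non-decreasing across iterations).  The integrated partial
likelihood reported for model ranking is the Laplace approximation

    ipl(theta) = pl(mode) - pen(mode) - 1/2 sum_f q_f log theta_f
                 - 1/2 log |H_bb|,

and the variances maximize ipl via bounded Brent searches, one variance at a
time.  Ties are handled with the Efron approximation.

Risk-set sums at the d event times are assembled from bucketed reverse
cumulative sums over rows sorted by entry and exit, so each Newton iteration
costs O(n m^2) for m model columns (fixed effects plus frailty indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["CoxFrailtyFit", "fit_cox_frailty", "breslow_baseline"]

_VAR_FLOOR = 1e-6
_VAR_CEIL = 10.0


def _prepare(start, stop, event):
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(start >= stop):
        raise ValueError("every interval needs start < stop")
    death_times = np.unique(stop[event == 1])
    j_start = np.searchsorted(death_times, start, side="right")
    j_stop = np.searchsorted(death_times, stop, side="right")
    # per death time: the tied death rows
    death_rows = [
        np.nonzero((event == 1) & (stop == t))[0] for t in death_times
    ]
    return death_times, j_start, j_stop, death_rows


def _bucket_reverse_cumsum(values, j_idx, d):
    """sum over rows with j_idx >= k+1, for k = 0..d-1 (reverse cumulative)."""
    shape = (d + 1,) + values.shape[1:]
    buckets = np.zeros(shape)
    np.add.at(buckets, j_idx, values)
    rev = np.cumsum(buckets[::-1], axis=0)[::-1]
    return rev[1:]  # rev[k+1] for k in 0..d-1


def _bucket_matmul(W, w, j_idx, d):
    """Bucketed reverse-cumulative sum of w_i W_i W_i^T at the d event times."""
    m = W.shape[1]
    order = np.argsort(j_idx, kind="stable")
    js = j_idx[order]
    splits = np.searchsorted(js, np.arange(1, d + 1))
    segs = np.split(order, splits)
    buckets = np.zeros((d + 1, m, m))
    for b, rows in enumerate(segs):
        if len(rows):
            Wb = W[rows]
            buckets[b] = (Wb * w[rows, None]).T @ Wb
    rev = np.cumsum(buckets[::-1], axis=0)[::-1]
    return rev[1:]


def _partial_loglik(eta, W, prep, need_grad=True, need_hess=True):
    """Efron partial log-likelihood with gradient/Hessian over the design W.

    All per-event-time Efron terms are evaluated in flattened vectorized form
    (one axis over the sum of tie multiplicities), so cost per call is
    O(n m^2) for the bucketed risk sums plus O(n_events m) for the ties.
    """
    death_times, j_start, j_stop, death_rows = prep
    d = len(death_times)
    n, m = W.shape
    shift = eta.max() if len(eta) else 0.0
    w = np.exp(eta - shift)

    if d == 0:
        return 0.0, (np.zeros(m) if need_grad else None), (
            np.zeros((m, m)) if need_hess else None)

    S0 = _bucket_reverse_cumsum(w, j_stop, d) - _bucket_reverse_cumsum(w, j_start, d)
    all_rows = np.concatenate(death_rows)
    dks = np.array([len(r) for r in death_rows])
    k_idx = np.repeat(np.arange(d), dks)            # event index per flat term
    frac = np.concatenate([np.arange(dk) / dk for dk in dks])
    s0d = np.zeros(d)
    np.add.at(s0d, k_idx, w[all_rows])
    den = S0[k_idx] - frac * s0d[k_idx]
    if np.any(den <= 0) or not np.all(np.isfinite(den)):
        # numerically degenerate risk sums (wildly divergent linear predictor)
        return -np.inf, (np.zeros(m) if need_grad else None), (
            np.eye(m) if need_hess else None)
    ll = float((eta[all_rows] - shift).sum() - np.log(den).sum())

    grad = hess = None
    if need_grad:
        wW = w[:, None] * W
        S1 = _bucket_reverse_cumsum(wW, j_stop, d) - _bucket_reverse_cumsum(wW, j_start, d)
        s1d = np.zeros((d, m))
        np.add.at(s1d, k_idx, wW[all_rows])
        a = np.zeros(d)                              # sum_j 1/den
        b = np.zeros(d)                              # sum_j frac_j/den
        np.add.at(a, k_idx, 1.0 / den)
        np.add.at(b, k_idx, frac / den)
        grad = W[all_rows].sum(axis=0) - (a @ S1 - b @ s1d)
        if need_hess:
            S2 = _bucket_matmul(W, w, j_stop, d) - _bucket_matmul(W, w, j_start, d)
            v = (S1[k_idx] - frac[:, None] * s1d[k_idx]) / den[:, None]
            hess = np.einsum("k,kij->ij", a, S2)
            for k in np.nonzero(b)[0]:
                rows = death_rows[k]
                s2d = (W[rows] * w[rows, None]).T @ W[rows]
                hess -= b[k] * s2d
            hess -= v.T @ v
    return ll, grad, hess


@dataclass
class CoxFrailtyFit:
    """A fitted mixed-effects Cox model."""

    label: str
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    variances: dict[str, float]
    ranef: dict[str, np.ndarray]
    loglik: float            # Laplace-integrated partial log-likelihood
    null_loglik: float       # fixed null (no covariates, no frailty)
    n_obs: int
    n_events: int
    converged: bool
    group_levels: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def zvalues(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * special.ndtr(-np.abs(self.zvalues))

    @property
    def n_parameters(self) -> int:
        return len(self.coef) + len(self.variances)

    @property
    def deviance_explained(self) -> float:
        """Model ranking statistic: integrated loglik minus the fixed-null loglik."""
        return self.loglik - self.null_loglik

    @property
    def loglik_chi2(self) -> float:
        return 2.0 * self.deviance_explained

    @property
    def model_pvalue(self) -> float:
        if self.n_parameters == 0:
            return 1.0
        return float(stats.chi2.sf(self.loglik_chi2, self.n_parameters))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.covariates,
                "coefficient": self.coef,
                "se": self.se,
                "p": self.pvalues,
                "hazard_ratio": self.hazard_ratios,
            }
        )


def _inner_newton(W, prep, penalty_diag, beta0, max_iter=60, tol=1e-10):
    """Maximize pl(theta) - 1/2 theta' P theta over all model columns."""
    m = W.shape[1]
    beta = beta0.copy()

    def pen_ll(beta):
        ll, _, _ = _partial_loglik(W @ beta if m else np.zeros(W.shape[0]),
                                   W, prep, need_grad=False, need_hess=False)
        return ll - 0.5 * float(beta @ (penalty_diag * beta))

    ll = pen_ll(beta)
    if not np.isfinite(ll):  # stale warm start after a large variance jump
        beta = np.zeros(m)
        ll = pen_ll(beta)
    converged = False
    H = np.zeros((m, m))
    for _ in range(max_iter):
        eta = W @ beta
        pl, g, H = _partial_loglik(eta, W, prep)
        g = g - penalty_diag * beta
        H = H + np.diag(penalty_diag)
        try:
            step = np.linalg.solve(H + 1e-9 * np.eye(m), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        improved = False
        for _ in range(30):
            cand = beta + t * step
            ll_new = pen_ll(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                improved = True
                break
            t *= 0.5
        if not improved:
            converged = True  # no ascent direction left: accept current point
            break
        beta = cand
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    # final Hessian at the optimum
    _, _, H = _partial_loglik(W @ beta, W, prep)
    H = H + np.diag(penalty_diag)
    return beta, ll, H, converged


def fit_cox_frailty(
    intervals: pd.DataFrame,
    covariates: list[str],
    random: tuple[str, ...] = ("fawn_id", "year"),
    variances: dict[str, float] | None = None,
    label: str | None = None,
    outer_sweeps: int = 2,
    brent_xatol: float = 1e-2,
) -> CoxFrailtyFit:
    """Fit a Cox model with Gaussian random intercepts on the log hazard.

    Parameters
    ----------
    intervals : counting-process rows with columns ``start, stop, event``
        plus the covariates and grouping columns.  Covariates should be
        standardized.
    covariates : fixed-effect columns (may be empty for a frailty-only or
        null model).
    random : grouping columns getting Gaussian random intercepts; pass ()
        for a plain Cox fit.
    variances : hold frailty variances fixed (0 removes the factor) instead
        of profiling them.
    """
    n = len(intervals)
    event = intervals["event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("need at least one event")
    prep = _prepare(intervals["start"], intervals["stop"], event)

    X = (
        np.column_stack([intervals[c].to_numpy(dtype=float) for c in covariates])
        if covariates
        else np.zeros((n, 0))
    )
    p = X.shape[1]

    groups, levels = {}, {}
    for g in random:
        codes, lev = pd.factorize(intervals[g])
        groups[g] = codes
        levels[g] = lev
    if variances is not None:
        groups = {g: c for g, c in groups.items() if variances.get(g, None) != 0}
    names = list(groups)
    q = [int(groups[g].max()) + 1 for g in names]
    offs = np.cumsum([p] + q)[:-1]
    m = p + sum(q)

    W = np.zeros((n, m))
    W[:, :p] = X
    for j, g in enumerate(names):
        W[np.arange(n), offs[j] + groups[g]] = 1.0

    # fixed null: no covariates, no random effects -> eta = 0
    null_ll, _, _ = _partial_loglik(np.zeros(n), np.zeros((n, 0)), prep,
                                    need_grad=False, need_hess=False)

    state = {"beta": np.zeros(m)}

    def integrated_ll(theta, tol=1e-10):
        pen = np.zeros(m)
        for j, g in enumerate(names):
            pen[offs[j]: offs[j] + q[j]] = 1.0 / theta[g]
        beta, pll, H, conv = _inner_newton(W, prep, pen, state["beta"], tol=tol)
        state["beta"] = beta
        ill = pll
        if names:
            Hbb = H[p:, p:]
            sign, logdet = np.linalg.slogdet(Hbb)
            if sign <= 0:
                return -np.inf, beta, H, conv
            ill = pll - 0.5 * logdet
            for j, g in enumerate(names):
                ill -= 0.5 * q[j] * np.log(theta[g])
        return ill, beta, H, conv

    if not names:
        beta, pll, H, conv = _inner_newton(W, prep, np.zeros(m), state["beta"])
        theta = {}
        ill = pll
    elif variances is not None:
        theta = {g: max(float(variances[g]), _VAR_FLOOR) for g in names}
        ill, beta, H, conv = integrated_ll(theta)
    else:
        theta = {g: 0.2 for g in names}
        for sweep in range(outer_sweeps):
            prev = dict(theta)
            for g in names:
                def neg(v, g=g):
                    th = dict(theta)
                    th[g] = v
                    return -integrated_ll(th, tol=1e-7)[0]

                if sweep == 0:
                    lo, hi, xatol = _VAR_FLOOR, 2.0, 5 * brent_xatol
                else:  # refine in a bracket around the current profile optimum
                    lo = max(_VAR_FLOOR, theta[g] / 3.0)
                    hi = min(_VAR_CEIL, max(3.0 * theta[g], 0.05))
                    xatol = brent_xatol
                res = optimize.minimize_scalar(
                    neg, bounds=(lo, hi), method="bounded",
                    options={"xatol": xatol},
                )
                theta[g] = float(res.x)
                if sweep == 0 and theta[g] > 0.95 * hi:  # optimum may exceed bracket
                    res = optimize.minimize_scalar(
                        neg, bounds=(hi, _VAR_CEIL), method="bounded",
                        options={"xatol": 5 * brent_xatol},
                    )
                    if -res.fun > -neg(theta[g]):
                        theta[g] = float(res.x)
            if sweep > 0 and all(abs(theta[g] - prev[g]) < 1e-2 for g in names):
                break
        ill, beta, H, conv = integrated_ll(theta)

    cov = np.linalg.inv(H) if m else np.zeros((0, 0))
    se = np.sqrt(np.diag(cov)[:p]) if p else np.zeros(0)
    ranef = {g: beta[offs[j]: offs[j] + q[j]] for j, g in enumerate(names)}
    var_out = {g: (0.0 if theta[g] <= 2 * _VAR_FLOOR else theta[g]) for g in names}
    return CoxFrailtyFit(
        label or (" + ".join(covariates) if covariates else "null"),
        list(covariates), beta[:p], se, var_out, ranef,
        float(ill), float(null_ll), n, n_events, bool(conv), levels,
    )


def breslow_baseline(
    fit: CoxFrailtyFit,
    intervals: pd.DataFrame,
    include_frailty: bool = True,
) -> pd.DataFrame:
    """Breslow cumulative baseline hazard at covariate 0, per year stratum.

    Returns one row per (year, event time) with the cumulative baseline
    hazard ``H0`` and baseline cumulative survival ``S0 = exp(-H0)``.
    Because cohorts are annual, risk sets are formed within year.
    """
    out = []
    for year, sub in intervals.groupby("year"):
        eta = np.zeros(len(sub))
        for c, b in zip(fit.covariates, fit.coef):
            eta += b * sub[c].to_numpy(dtype=float)
        if include_frailty:
            for g, modes in fit.ranef.items():
                lev = {v: i for i, v in enumerate(fit.group_levels[g])}
                codes = sub[g].map(lev).to_numpy()
                eta += modes[codes.astype(int)]
        w = np.exp(eta)
        start = sub["start"].to_numpy(dtype=float)
        stop = sub["stop"].to_numpy(dtype=float)
        event = sub["event"].to_numpy(dtype=int)
        times = np.unique(stop[event == 1])
        h0 = 0.0
        for t in times:
            at_risk = (start < t) & (t <= stop)
            d = int(((stop == t) & (event == 1)).sum())
            h0 += d / w[at_risk].sum()
            out.append({"year": year, "time": float(t), "H0": h0, "S0": np.exp(-h0)})
        if len(times) == 0:
            out.append({"year": year, "time": np.inf, "H0": 0.0, "S0": 1.0})
    return pd.DataFrame(out)
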