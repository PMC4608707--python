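"""Binomial GLMM with crossed Gaussian random intercepts, Laplace maximum likelihood.

The marginal likelihood integrates the Bernoulli likelihood over Gaussian
random intercepts for each grouping factor (here: fawn and year).  For fixed
variances, the joint penalized log-likelihood in (beta, b) is maximized by
Newton iterations with step-halving; the Laplace approximation to the
marginal log-likelihood is

    l(theta) = l_joint(mode) - 1/2 sum_f q_f log theta_f - 1/2 log|H_bb|

with H_bb the (penalized) negative Hessian in b at the mode (the 2*pi terms
cancel exactly).  Variances are then maximized by a derivative-free outer
search on the log scale.  The joint Hessian is assembled from per-group
aggregations, so cost is linear in the number of rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["GLMMFit", "fit_logistic_glmm"]

_VAR_FLOOR = 1e-8


@dataclass
class GLMMFit:
    """Maximum-likelihood fit of a logistic model with Gaussian random intercepts."""

    coef: np.ndarray                 # fixed effects, intercept first
    se: np.ndarray
    coef_names: list[str]
    variances: dict[str, float]      # per grouping factor
    ranef: dict[str, np.ndarray]     # posterior modes per level
    loglik: float                    # Laplace marginal (plain loglik if no groups)
    n_obs: int
    converged: bool

    @property
    def zvalues(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * special.ndtr(-np.abs(self.zvalues))

    def linear_predictor(self, X: np.ndarray, groups: dict[str, np.ndarray] | None = None
                         ) -> np.ndarray:
        """Fitted linear predictor; includes random-intercept modes if groups given."""
        eta = np.asarray(X, dtype=float) @ self.coef
        if groups:
            for name, codes in groups.items():
                eta = eta + self.ranef[name][np.asarray(codes, dtype=int)]
        return eta


def _joint_newton(y, X, group_codes, q_sizes, theta, beta0, b0, max_iter=100, tol=1e-10):
    """Maximize the penalized joint log-likelihood over (beta, b).

    Returns (beta, b_list, penalized loglik, H) where H is the full negative
    Hessian (including the 1/theta penalty on the b blocks).
    """
    n, p = X.shape
    names = list(group_codes)
    q = [q_sizes[g] for g in names]
    m = p + sum(q)
    offs = np.cumsum([p] + q)[:-1]

    beta = beta0.copy()
    b = [np.array(b0[g], dtype=float, copy=True) for g in names]

    def eta_of(beta, b):
        eta = X @ beta
        for g, bg in zip(names, b):
            eta = eta + bg[group_codes[g]]
        return eta

    def pen_ll(beta, b):
        eta = eta_of(beta, b)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        for g, bg in zip(names, b):
            ll -= 0.5 * float(bg @ bg) / theta[g]
        return ll

    ll = pen_ll(beta, b)
    converged = False
    H = None
    for _ in range(max_iter):
        eta = eta_of(beta, b)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        resid = y - mu

        grad = np.empty(m)
        grad[:p] = X.T @ resid
        for j, (g, bg) in enumerate(zip(names, b)):
            grad[offs[j]: offs[j] + q[j]] = (
                np.bincount(group_codes[g], weights=resid, minlength=q[j]) - bg / theta[g]
            )

        H = np.zeros((m, m))
        Xw = X * w[:, None]
        H[:p, :p] = X.T @ Xw
        for j, g in enumerate(names):
            cg = group_codes[g]
            sl = slice(offs[j], offs[j] + q[j])
            for col in range(p):
                H[sl, col] = np.bincount(cg, weights=Xw[:, col], minlength=q[j])
            H[:p, sl] = H[sl, :p].T
            dg = np.bincount(cg, weights=w, minlength=q[j])
            H[sl, sl] = np.diag(dg + 1.0 / theta[g])
            for j2 in range(j + 1, len(names)):
                g2 = names[j2]
                sl2 = slice(offs[j2], offs[j2] + q[j2])
                cross = np.zeros((q[j], q[j2]))
                np.add.at(cross, (cg, group_codes[g2]), w)
                H[sl, sl2] = cross
                H[sl2, sl] = cross.T

        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(m), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]

        # step-halving keeps the penalized log-likelihood monotone
        t = 1.0
        for _ in range(30):
            beta_new = beta + t * step[:p]
            b_new = [bg + t * step[offs[j]: offs[j] + q[j]] for j, bg in enumerate(b)]
            ll_new = pen_ll(beta_new, b_new)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta, b = beta_new, b_new
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return beta, {g: bg for g, bg in zip(names, b)}, ll, H, converged


def _plain_logistic(y, X, max_iter=100, tol=1e-12):
    """Newton/IRLS logistic regression; returns (beta, loglik, cov)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll = float(np.sum(y * (X @ beta) - np.logaddexp(0.0, X @ beta)))
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = float(np.sum(y * (X @ cand) - np.logaddexp(0.0, X @ cand)))
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = cand
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            break
        ll = ll_new
    eta = X @ beta
    mu = special.expit(eta)
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    return beta, ll, np.linalg.inv(H)


def fit_logistic_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
    coef_names: list[str] | None = None,
    variances: dict[str, float] | None = None,
    outer_maxiter: int = 120,
) -> GLMMFit:
    """Fit the use-availability logistic model, optionally with random intercepts.

    Parameters
    ----------
    y : 0/1 response (1 = used point, 0 = availability point).
    X : design matrix including the intercept column.
    groups : mapping factor name -> integer level codes per row (crossed
        random intercepts on the model intercept).  None or empty fits a
        plain logistic regression.
    variances : if given, the random-intercept variances are held fixed at
        these values instead of being estimated (0 collapses the factor).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be 0/1")
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(X.shape[1])]

    groups = {
        g: np.asarray(c, dtype=int) for g, c in (groups or {}).items()
    }
    # factors with fixed zero variance drop out of the model entirely
    if variances is not None:
        groups = {g: c for g, c in groups.items() if variances.get(g, None) != 0}

    if not groups:
        beta, ll, cov = _plain_logistic(y, X)
        return GLMMFit(beta, np.sqrt(np.diag(cov)), coef_names, {}, {}, ll,
                       len(y), True)

    q_sizes = {g: int(c.max()) + 1 for g, c in groups.items()}
    p = X.shape[1]
    names = list(groups)

    state = {"beta": np.zeros(p), "b": {g: np.zeros(q_sizes[g]) for g in names}}

    def laplace_ll(theta):
        beta, b, pll, H, _ = _joint_newton(
            y, X, groups, q_sizes, theta, state["beta"], state["b"]
        )
        state["beta"], state["b"] = beta, b  # warm start the next evaluation
        Hbb = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Hbb)
        if sign <= 0:
            return -np.inf, None, None, None
        ll = pll - 0.5 * logdet
        for g in names:
            ll -= 0.5 * q_sizes[g] * np.log(theta[g])
        return ll, beta, b, H

    if variances is not None:
        theta = {g: max(float(variances[g]), _VAR_FLOOR) for g in names}
        ll, beta, b, H = laplace_ll(theta)
        converged = True
    else:
        def neg(logtheta):
            theta = {g: max(float(np.exp(lt)), _VAR_FLOOR)
                     for g, lt in zip(names, logtheta)}
            val = laplace_ll(theta)[0]
            return -val if np.isfinite(val) else 1e12

        res = optimize.minimize(
            neg, np.full(len(names), np.log(0.1)), method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": outer_maxiter},
        )
        theta = {g: max(float(np.exp(lt)), _VAR_FLOOR) for g, lt in zip(names, res.x)}
        ll, beta, b, H = laplace_ll(theta)
        converged = bool(res.success) or res.fun < np.inf

    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov)[:p])
    var_out = {g: (0.0 if theta[g] <= 10 * _VAR_FLOOR else theta[g]) for g in names}
    return GLMMFit(beta, se, coef_names, var_out, b, ll, len(y), converged)
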