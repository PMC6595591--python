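"""Fixed- and random-intercept logistic and cumulative-logit models.

Rankability needs two companion fits per indicator:

* a **random-intercept** model, whose between-hospital variance ``tau^2``
  is the signal term.  The marginal likelihood integrates the hospital
  intercept out of the conditional (binary or proportional-odds) likelihood
  against a normal density; the integral is evaluated by adaptive
  Gauss-Hermite quadrature (nodes re-centred at each hospital's posterior
  mode, scaled by the posterior curvature) and maximised by quasi-Newton
  with gradients from Fisher's identity (posterior expectations of the
  complete-data score).

* a **fixed-effects** model with one effect per hospital, whose Wald
  standard errors ``s_j`` are the noise term.  The binary variant uses a
  no-intercept parameterisation (K hospital indicators) fitted by Newton
  iterations on the arrow-structured information matrix (diagonal over
  hospital effects plus one slope row), which keeps each iteration O(N)
  at any number of hospitals.  The ordinal variant is a proportional-odds
  model with K hospital effects under a sum-to-zero constraint (identifying
  them against the thresholds), fitted by an exact Newton method on the
  structured Hessian — every hospital then contributes an effect and a
  standard error.

Hospitals in which the fixed effect is not identified (no events or all
events for the binary outcome; every patient in one extreme level for the
ordinal outcome) are excluded from the fixed fit and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, roots_hermite

__all__ = [
    "FixedFitBinary",
    "FixedFitOrdinal",
    "RandomFitBinary",
    "RandomFitOrdinal",
    "fit_logistic_fixed",
    "fit_logistic_random",
    "fit_ordinal_fixed",
    "fit_ordinal_random",
]

_TAU_FLOOR = 1e-4  # SD scale; tau below this is reported as a boundary (zero) fit


# --------------------------------------------------------------------------
# result containers


@dataclass
class FixedFitBinary:
    hospital_ids: np.ndarray
    hospital_effects: np.ndarray
    hospital_ses: np.ndarray
    beta_hat: float | None
    excluded_hospitals: list
    converged: bool
    loglik: float

    def __post_init__(self) -> None:
        if np.any(self.hospital_ses <= 0):
            raise ValueError("hospital standard errors must be positive")


@dataclass
class RandomFitBinary:
    tau2_hat: float
    alpha0_hat: float
    beta_hat: float | None
    loglik: float
    converged: bool
    n_quad: int

    def __post_init__(self) -> None:
        if self.tau2_hat < 0:
            raise ValueError("tau2_hat must be non-negative")


@dataclass
class FixedFitOrdinal:
    thresholds: np.ndarray
    hospital_ids: np.ndarray
    hospital_effects: np.ndarray
    hospital_ses: np.ndarray
    beta_hat: float | None
    excluded_hospitals: list
    converged: bool
    loglik: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(self.hospital_ses <= 0):
            raise ValueError("hospital standard errors must be positive")


@dataclass
class RandomFitOrdinal:
    thresholds: np.ndarray
    beta_hat: float | None
    tau2_hat: float
    loglik: float
    converged: bool
    n_quad: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.tau2_hat < 0:
            raise ValueError("tau2_hat must be non-negative")


# --------------------------------------------------------------------------
# data extraction


def _extract(data: pd.DataFrame, column: str):
    """Return (y, x, group codes 0..K-1, sorted hospital ids), rows sorted by hospital."""
    hosp = np.asarray(data["hospital_id"])
    y = np.asarray(data[column], dtype=float)
    x = np.asarray(data["x"], dtype=float)
    order = np.argsort(hosp, kind="stable")
    hosp, y, x = hosp[order], y[order], x[order]
    ids, g = np.unique(hosp, return_inverse=True)
    if ids.size < 2:
        raise ValueError("need at least 2 hospitals")
    return y, x, g, ids


def _indicator_column(indicator: str) -> str:
    if indicator not in {"y1", "y2", "y3"}:
        raise ValueError(f"indicator must be 'y1', 'y2' or 'y3', got {indicator!r}")
    return indicator


# --------------------------------------------------------------------------
# fixed-effects binary logistic (K hospital indicators, no global intercept)


def fit_logistic_fixed(
    data: pd.DataFrame, indicator: str = "y1", include_x: bool = True
) -> FixedFitBinary:
    """MLE of the fixed-effects logistic model ``logit Pr(Y=1) = alpha_j [+ beta x]``.

    Every retained hospital gets its own effect and Wald standard error.
    Hospitals with 0% or 100% events are excluded (their effect diverges)
    and listed in ``excluded_hospitals``.
    """
    y, x, g, ids = _extract(data, _indicator_column(indicator))
    K = ids.size
    events = np.bincount(g, weights=y, minlength=K)
    counts = np.bincount(g, minlength=K)
    degenerate = (events == 0) | (events == counts)
    excluded = [int(i) for i in ids[degenerate]]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} hospital(s) with all-0 or all-1 outcomes: {excluded}",
            stacklevel=2,
        )
        keep_rows = ~degenerate[g]
        y, x = y[keep_rows], x[keep_rows]
        ids = ids[~degenerate]
        g = np.unique(np.asarray(g)[keep_rows], return_inverse=True)[1]
        K = ids.size
        if K < 2:
            raise ValueError("fewer than 2 identifiable hospitals remain")

    # Newton iterations exploiting the arrow structure of the information
    # matrix: diagonal over hospital effects plus one slope row/column.
    counts = np.bincount(g, minlength=K)
    rates = np.clip(np.bincount(g, weights=y, minlength=K) / counts,
                    0.5 / counts, 1 - 0.5 / counts)
    h = np.asarray(logit(rates), dtype=float)
    beta = 0.0

    def loglik(h, beta):
        eta = h[g] + (beta * x if include_x else 0.0)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(h, beta)
    converged = False
    for _ in range(60):
        eta = h[g] + (beta * x if include_x else 0.0)
        p = expit(eta)
        w = p * (1 - p)
        gh = np.bincount(g, weights=y - p, minlength=K)
        D = np.clip(np.bincount(g, weights=w, minlength=K), 1e-12, None)
        if include_x:
            gb = float((y - p) @ x)
            c = np.bincount(g, weights=w * x, minlength=K)
            s = float(w @ (x * x))
            schur = max(s - float(c**2 @ (1.0 / D)), 1e-12)
            db = (gb - float(c @ (gh / D))) / schur
            dh = (gh - c * db) / D
        else:
            db, dh = 0.0, gh / D
        grad_norm = max(np.max(np.abs(gh)), abs(gb) if include_x else 0.0)
        t = 1.0
        for _ls in range(30):
            ll_new = loglik(h + t * dh, beta + t * db)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        h, beta, ll = h + t * dh, beta + t * db, ll_new
        if grad_norm < 1e-8 or np.max(np.abs(t * dh)) < 1e-10:
            converged = True
            break

    eta = h[g] + (beta * x if include_x else 0.0)
    p = expit(eta)
    w = p * (1 - p)
    D = np.clip(np.bincount(g, weights=w, minlength=K), 1e-12, None)
    if include_x:
        c = np.bincount(g, weights=w * x, minlength=K)
        s = float(w @ (x * x))
        var_beta = 1.0 / max(s - float(c**2 @ (1.0 / D)), 1e-12)
        var_h = 1.0 / D + (c / D) ** 2 * var_beta
    else:
        var_h = 1.0 / D
    return FixedFitBinary(
        hospital_ids=ids,
        hospital_effects=h,
        hospital_ses=np.sqrt(var_h),
        beta_hat=float(beta) if include_x else None,
        excluded_hospitals=excluded,
        converged=converged,
        loglik=float(loglik(h, beta)),
    )


# --------------------------------------------------------------------------
# proportional-odds machinery (shared by fixed and random ordinal fits)
#
# Model: Pr(Y <= l) = expit(c_l - u), u = hospital effect + beta * x.
# Larger u shifts mass towards higher (more severe) levels.


def _po_row_derivs(lev: np.ndarray, u: np.ndarray, c: np.ndarray):
    """Per-row log-likelihood pieces of the cumulative-logit model.

    Returns (ll, per-row derivative arrays) where derivatives are with
    respect to the upper/lower threshold linear predictors ``eta_hi = c_l - u``
    and ``eta_lo = c_{l-1} - u``.
    """
    M = c.size  # number of thresholds = L - 1
    has_hi = lev < M
    has_lo = lev > 0
    eta_hi = np.where(has_hi, c[np.minimum(lev, M - 1)] - u, np.inf)
    eta_lo = np.where(has_lo, c[np.maximum(lev - 1, 0)] - u, -np.inf)
    F_hi = np.where(has_hi, expit(eta_hi), 1.0)
    F_lo = np.where(has_lo, expit(eta_lo), 0.0)
    f_hi = np.where(has_hi, F_hi * (1 - F_hi), 0.0)
    f_lo = np.where(has_lo, F_lo * (1 - F_lo), 0.0)
    fp_hi = f_hi * (1 - 2 * F_hi)
    fp_lo = f_lo * (1 - 2 * F_lo)
    P = np.clip(F_hi - F_lo, 1e-300, None)
    ll = float(np.sum(np.log(P)))
    g_hi = f_hi / P
    g_lo = -f_lo / P
    h_hihi = fp_hi / P - g_hi**2
    h_lolo = -fp_lo / P - (f_lo / P) ** 2
    h_hilo = f_hi * f_lo / P**2
    return ll, g_hi, g_lo, h_hihi, h_lolo, h_hilo


def _po_u_derivs(lev: np.ndarray, u: np.ndarray, c: np.ndarray):
    """Log-likelihood and per-row first/second derivatives w.r.t. u."""
    ll, g_hi, g_lo, h_hihi, h_lolo, h_hilo = _po_row_derivs(lev, u, c)
    g_u = -(g_hi + g_lo)
    S = h_hihi + 2 * h_hilo + h_lolo  # d2 logP / du2, <= 0 (log-concave)
    return ll, g_u, S


def _levels(data: pd.DataFrame):
    yo = np.asarray(data["y_ordinal"])
    values = np.unique(yo)
    if values.size < 2:
        raise ValueError("need at least 2 observed ordinal levels")
    return values


def _start_thresholds(lev: np.ndarray, M: int) -> np.ndarray:
    cum = np.cumsum(np.bincount(lev, minlength=M + 1))[:M] / lev.size
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    c = logit(cum)
    # enforce strict increase in pathological starts
    for m in range(1, M):
        c[m] = max(c[m], c[m - 1] + 1e-6)
    return c


def fit_ordinal_fixed(data: pd.DataFrame, include_x: bool = True) -> FixedFitOrdinal:
    """Proportional-odds MLE with one effect per hospital, sum-to-zero constrained.

    ``Pr(Y <= l) = expit(c_l - h_j - beta x)`` with ``sum_j h_j = 0``; the
    constraint identifies the hospital effects against the thresholds while
    treating every hospital symmetrically.  Newton iterations use the exact
    gradient and Hessian; standard errors come from the bordered (equality-
    constrained) information matrix.  Hospitals whose patients all sit in a
    single extreme level are excluded.
    """
    values = _levels(data)
    y, x, g, ids = _extract(data, "y_ordinal")
    lev = np.searchsorted(values, y.astype(values.dtype))
    M = values.size - 1
    K = ids.size
    counts = np.bincount(g, minlength=K)
    at_min = np.bincount(g, weights=(lev == 0), minlength=K) == counts
    at_max = np.bincount(g, weights=(lev == M), minlength=K) == counts
    degenerate = at_min | at_max
    excluded = [int(i) for i in ids[degenerate]]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} hospital(s) with all patients in one extreme level: {excluded}",
            stacklevel=2,
        )
        keep = ~degenerate[g]
        lev, x = lev[keep], x[keep]
        ids = ids[~degenerate]
        g = np.unique(np.asarray(g)[keep], return_inverse=True)[1]
        K = ids.size
        if K < 2:
            raise ValueError("fewer than 2 identifiable hospitals remain")

    nb = 1 if include_x else 0
    P_dim = M + K + nb
    c = _start_thresholds(lev, M)
    h = np.zeros(K)
    beta = 0.0
    idx_hi = np.minimum(lev, M - 1)
    idx_lo = np.maximum(lev - 1, 0)
    has_hi = lev < M
    has_lo = lev > 0

    def assemble(c, h, beta):
        u = h[g] + (beta * x if include_x else 0.0)
        ll, g_hi, g_lo, h_hihi, h_lolo, h_hilo = _po_row_derivs(lev, u, c)
        g_u = -(g_hi + g_lo)
        S = h_hihi + 2 * h_hilo + h_lolo
        grad = np.zeros(P_dim)
        np.add.at(grad, idx_hi, np.where(has_hi, g_hi, 0.0))
        np.add.at(grad, idx_lo, np.where(has_lo, g_lo, 0.0))
        grad[M : M + K] = np.bincount(g, weights=g_u, minlength=K)
        if include_x:
            grad[M + K] = float(g_u @ x)
        H = np.zeros((P_dim, P_dim))
        # threshold block
        np.add.at(H, (idx_hi, idx_hi), np.where(has_hi, h_hihi, 0.0))
        np.add.at(H, (idx_lo, idx_lo), np.where(has_lo, h_lolo, 0.0))
        both = has_hi & has_lo
        np.add.at(H, (idx_hi, idx_lo), np.where(both, h_hilo, 0.0))
        np.add.at(H, (idx_lo, idx_hi), np.where(both, h_hilo, 0.0))
        # threshold x u cross terms
        cu_hi = -(h_hihi + h_hilo)  # d2 / d c_{l} d u
        cu_lo = -(h_lolo + h_hilo)  # d2 / d c_{l-1} d u
        for m in range(M):
            row_hi = np.where(has_hi & (idx_hi == m), cu_hi, 0.0)
            row_lo = np.where(has_lo & (idx_lo == m), cu_lo, 0.0)
            w = row_hi + row_lo
            H[m, M : M + K] += np.bincount(g, weights=w, minlength=K)
            if include_x:
                H[m, M + K] += float(w @ x)
        H[M : M + K, :M] = H[:M, M : M + K].T
        # hospital / slope block
        H[M + np.arange(K), M + np.arange(K)] += np.bincount(g, weights=S, minlength=K)
        if include_x:
            hb = np.bincount(g, weights=S * x, minlength=K)
            H[M : M + K, M + K] += hb
            H[M + K, M : M + K] += hb
            H[M + K, M + K] += float(S @ (x * x))
            H[M + K, :M] = H[:M, M + K]
        return ll, grad, H

    # bordered Newton: maximize ll subject to sum(h) = 0
    A = np.zeros(P_dim)
    A[M : M + K] = 1.0
    theta = np.concatenate([c, h, [beta] if include_x else []])
    ll_old = -np.inf
    converged = False
    B = None
    for _ in range(60):
        c, h = theta[:M], theta[M : M + K]
        beta = theta[M + K] if include_x else 0.0
        ll, grad, H = assemble(c, h, beta)
        B = np.zeros((P_dim + 1, P_dim + 1))
        B[:P_dim, :P_dim] = -H
        B[:P_dim, P_dim] = A
        B[P_dim, :P_dim] = A
        rhs = np.concatenate([grad, [-float(A @ theta)]])
        try:
            step = np.linalg.solve(B, rhs)[:P_dim]
        except np.linalg.LinAlgError:
            break
        # damped line search on the constrained surface
        t, ll_new = 1.0, -np.inf
        for _ls in range(30):
            cand = theta + t * step
            cc = cand[:M]
            if np.all(np.diff(cc) > 0):
                u = cand[M : M + K][g] + (cand[M + K] * x if include_x else 0.0)
                ll_new = _po_row_derivs(lev, u, cc)[0]
                if ll_new >= ll - 1e-12:
                    break
            t /= 2
        theta = theta + t * step
        if np.max(np.abs(grad - A * float(grad @ A) / K)) < 1e-6 or np.max(np.abs(t * step)) < 1e-8:
            converged = True
            # refresh derivatives at the final point
            c, h = theta[:M], theta[M : M + K]
            beta = theta[M + K] if include_x else 0.0
            ll, grad, H = assemble(c, h, beta)
            B[:P_dim, :P_dim] = -H
            break
        ll_old = ll

    cov = np.linalg.inv(B)[:P_dim, :P_dim]
    ses = np.sqrt(np.clip(np.diag(cov)[M : M + K], 1e-300, None))
    return FixedFitOrdinal(
        thresholds=theta[:M].copy(),
        hospital_ids=ids,
        hospital_effects=theta[M : M + K].copy(),
        hospital_ses=ses,
        beta_hat=float(theta[M + K]) if include_x else None,
        excluded_hospitals=excluded,
        converged=converged,
        loglik=float(ll),
    )


# --------------------------------------------------------------------------
# adaptive Gauss-Hermite marginal likelihoods


def _gh_nodes(n_quad: int):
    z, w = roots_hermite(n_quad)
    return z, np.log(w)


class _AGQBinary:
    """Marginal negative log-likelihood of the random-intercept logistic model.

    Parameters are (alpha0[, beta], tau); the hospital intercept
    a_j ~ N(alpha0, tau^2) is integrated out per hospital by adaptive
    Gauss-Hermite quadrature.
    """

    def __init__(self, y, x, g, K, include_x, n_quad):
        self.y, self.x, self.g, self.K = y, x, g, K
        self.include_x = include_x
        self.z, self.logw = _gh_nodes(n_quad)
        self.modes = None  # warm start across evaluations

    def _conditional(self, a_row, off):
        eta = a_row + off
        # per-row Bernoulli log-likelihood and mean
        return self.y * eta - np.logaddexp(0.0, eta)

    def __call__(self, params):
        y, x, g, K = self.y, self.x, self.g, self.K
        if self.include_x:
            alpha0, beta, tau = params
            off = beta * x
        else:
            alpha0, tau = params
            beta, off = None, 0.0
        tau = max(tau, _TAU_FLOOR)
        tau2 = tau * tau
        # posterior modes (Newton, concave)
        a = self.modes if self.modes is not None else np.full(K, alpha0)
        for _ in range(50):
            eta = a[g] + off
            p = expit(eta)
            score = np.bincount(g, weights=y - p, minlength=K) - (a - alpha0) / tau2
            curv = np.bincount(g, weights=p * (1 - p), minlength=K) + 1.0 / tau2
            step = np.clip(score / curv, -4.0, 4.0)
            a = a + step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.modes = a
        eta = a[g] + off
        p = expit(eta)
        curv = np.bincount(g, weights=p * (1 - p), minlength=K) + 1.0 / tau2
        sigma = 1.0 / np.sqrt(curv)

        Q = self.z.size
        terms = np.empty((Q, K))
        s_a0 = np.empty((Q, K))  # complete-data score pieces per node
        s_tau = np.empty((Q, K))
        s_beta = np.empty((Q, K)) if self.include_x else None
        for q in range(Q):
            aq = a + np.sqrt(2.0) * sigma * self.z[q]
            cond = self._conditional(aq[g], off)
            cond_j = np.bincount(g, weights=cond, minlength=K)
            dev = aq - alpha0
            logprior = -0.5 * np.log(2 * np.pi * tau2) - dev**2 / (2 * tau2)
            terms[q] = self.logw[q] + self.z[q] ** 2 + cond_j + logprior
            s_a0[q] = dev / tau2
            s_tau[q] = dev**2 / tau2 / tau - 1.0 / tau
            if self.include_x:
                r = self.y - expit(aq[g] + off)
                s_beta[q] = np.bincount(g, weights=r * x, minlength=K)
        m = terms.max(axis=0)
        sumexp = np.exp(terms - m).sum(axis=0)
        loglik = float(np.sum(m + np.log(sumexp) + 0.5 * np.log(2.0) + np.log(sigma)))
        pi = np.exp(terms - m) / sumexp  # posterior quadrature weights (Q, K)
        g_a0 = float(np.sum(pi * s_a0))
        g_tau = float(np.sum(pi * s_tau))
        if self.include_x:
            g_beta = float(np.sum(pi * s_beta))
            grad = np.array([g_a0, g_beta, g_tau])
        else:
            grad = np.array([g_a0, g_tau])
        return -loglik, -grad


def _start_binary(y, x, g, K, include_x):
    counts = np.bincount(g)
    rates = np.bincount(g, weights=y) / counts
    pooled = float(np.clip(y.mean(), 1e-4, 1 - 1e-4))
    alpha0 = float(logit(pooled))
    rates = np.clip(rates, 0.5 / counts, 1 - 0.5 / counts)
    lo = logit(rates)
    within = np.mean(1.0 / (counts * rates * (1 - rates)))
    tau0 = float(np.sqrt(max(np.var(lo) - within, 0.0025)))
    tau0 = float(np.clip(tau0, 0.05, 2.0))
    if include_x:
        # a few pooled Newton steps for the slope start
        b = np.array([alpha0, 0.0])
        X = np.column_stack([np.ones_like(x), x])
        for _ in range(4):
            p = expit(X @ b)
            W = p * (1 - p)
            gvec = X.T @ (y - p)
            H = (X * W[:, None]).T @ X
            b = b + np.linalg.solve(H, gvec)
        return np.array([b[0], b[1], tau0])
    return np.array([alpha0, tau0])


def fit_logistic_random(
    data: pd.DataFrame, indicator: str = "y1", include_x: bool = True, n_quad: int = 15
) -> RandomFitBinary:
    """Marginal MLE of ``logit Pr(Y=1) = a_j [+ beta x]``, ``a_j ~ N(alpha0, tau^2)``.

    The random intercept is integrated out by adaptive Gauss-Hermite
    quadrature (default 15 nodes; 1 node is the Laplace approximation).
    ``tau`` is estimated on the SD scale with the boundary value 0 permitted.
    """
    y, x, g, ids = _extract(data, _indicator_column(indicator))
    K = ids.size
    obj = _AGQBinary(y, x, g, K, include_x, n_quad)
    x0 = _start_binary(y, x, g, K, include_x)
    bounds = ([(None, None), (None, None), (_TAU_FLOOR, 10.0)] if include_x
              else [(None, None), (_TAU_FLOOR, 10.0)])
    res = minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-6})
    params = res.x
    tau = params[-1]
    tau2 = 0.0 if tau <= _TAU_FLOOR * (1 + 1e-9) else float(tau**2)
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
    return RandomFitBinary(
        tau2_hat=tau2,
        alpha0_hat=float(params[0]),
        beta_hat=float(params[1]) if include_x else None,
        loglik=float(-res.fun),
        converged=converged,
        n_quad=n_quad,
    )


class _AGQOrdinal:
    """Marginal negative log-likelihood of the random-intercept PO model.

    Parameters are (zeta_1, log-increments zeta_2..zeta_M[, beta], tau):
    thresholds c_m = zeta_1 + sum_{k<=m} exp(zeta_k) are strictly increasing
    by construction; a_j ~ N(0, tau^2) enters as Pr(Y<=l) = expit(c_l - beta x - a_j).
    """

    def __init__(self, lev, x, g, K, M, include_x, n_quad):
        self.lev, self.x, self.g, self.K, self.M = lev, x, g, K, M
        self.include_x = include_x
        self.z, self.logw = _gh_nodes(n_quad)
        self.modes = None
        self.idx_hi = np.minimum(lev, M - 1)
        self.idx_lo = np.maximum(lev - 1, 0)
        self.has_hi = lev < M
        self.has_lo = lev > 0

    def thresholds(self, zeta):
        c = np.empty(self.M)
        c[0] = zeta[0]
        if self.M > 1:
            c[1:] = zeta[0] + np.cumsum(np.exp(zeta[1 : self.M]))
        return c

    def __call__(self, params):
        lev, x, g, K, M = self.lev, self.x, self.g, self.K, self.M
        zeta = params[:M]
        if self.include_x:
            beta = params[M]
            off = beta * x
        else:
            off = 0.0
        tau = max(params[-1], _TAU_FLOOR)
        tau2 = tau * tau
        c = self.thresholds(zeta)

        a = self.modes if self.modes is not None else np.zeros(K)
        for _ in range(50):
            u = off + a[g]
            _, g_u, S = _po_u_derivs(lev, u, c)
            score = np.bincount(g, weights=g_u, minlength=K) - a / tau2
            curv = np.bincount(g, weights=-S, minlength=K) + 1.0 / tau2
            step = np.clip(score / curv, -4.0, 4.0)
            a = a + step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.modes = a
        u = off + a[g]
        _, g_u, S = _po_u_derivs(lev, u, c)
        curv = np.bincount(g, weights=-S, minlength=K) + 1.0 / tau2
        sigma = 1.0 / np.sqrt(curv)

        Q = self.z.size
        terms = np.empty((Q, K))
        s_tau = np.empty((Q, K))
        s_c = np.empty((Q, M, K))
        s_beta = np.empty((Q, K)) if self.include_x else None
        for q in range(Q):
            aq = a + np.sqrt(2.0) * sigma * self.z[q]
            u = off + aq[g]
            ll_row, g_hi, g_lo, *_ = _po_row_derivs(lev, u, c)
            logP = np.log(np.clip(
                np.where(self.has_hi, expit(c[self.idx_hi] - u), 1.0)
                - np.where(self.has_lo, expit(c[self.idx_lo] - u), 0.0),
                1e-300, None))
            cond_j = np.bincount(g, weights=logP, minlength=K)
            logprior = -0.5 * np.log(2 * np.pi * tau2) - aq**2 / (2 * tau2)
            terms[q] = self.logw[q] + self.z[q] ** 2 + cond_j + logprior
            s_tau[q] = aq**2 / tau2 / tau - 1.0 / tau
            gc = np.zeros((M, K))
            wh = np.where(self.has_hi, g_hi, 0.0)
            wl = np.where(self.has_lo, g_lo, 0.0)
            np.add.at(gc, (self.idx_hi, g), wh)
            np.add.at(gc, (self.idx_lo, g), wl)
            s_c[q] = gc
            if self.include_x:
                g_u_row = -(g_hi + g_lo)
                s_beta[q] = np.bincount(g, weights=g_u_row * x, minlength=K)
        m = terms.max(axis=0)
        sumexp = np.exp(terms - m).sum(axis=0)
        loglik = float(np.sum(m + np.log(sumexp) + 0.5 * np.log(2.0) + np.log(sigma)))
        pi = np.exp(terms - m) / sumexp

        grad_c = np.einsum("qk,qmk->m", pi, s_c)
        # chain rule to the increment parameterisation
        grad_zeta = np.empty(M)
        grad_zeta[0] = grad_c.sum()
        for k in range(1, M):
            grad_zeta[k] = grad_c[k:].sum() * np.exp(zeta[k])
        g_tau = float(np.sum(pi * s_tau))
        if self.include_x:
            grad = np.concatenate([grad_zeta, [float(np.sum(pi * s_beta))], [g_tau]])
        else:
            grad = np.concatenate([grad_zeta, [g_tau]])
        return -loglik, -grad


def fit_ordinal_random(
    data: pd.DataFrame, include_x: bool = True, n_quad: int = 15
) -> RandomFitOrdinal:
    """Marginal MLE of the random-intercept proportional-odds model.

    ``Pr(Y<=l) = expit(c_l - beta x - a_j)``, ``a_j ~ N(0, tau^2)`` (the
    thresholds absorb the mean).  Integration and optimisation follow
    :func:`fit_logistic_random`.
    """
    values = _levels(data)
    y, x, g, ids = _extract(data, "y_ordinal")
    lev = np.searchsorted(values, y.astype(values.dtype))
    M = values.size - 1
    K = ids.size
    obj = _AGQOrdinal(lev, x, g, K, M, include_x, n_quad)

    # start from the pooled proportional-odds fit
    c0, beta0 = _fit_po_pooled(lev, x, M, include_x)
    zeta0 = np.empty(M)
    zeta0[0] = c0[0]
    if M > 1:
        zeta0[1:] = np.log(np.clip(np.diff(c0), 1e-4, None))
    x0 = np.concatenate([zeta0, [beta0] if include_x else [], [0.3]])
    nb = 1 if include_x else 0
    bounds = [(None, None)] * (M + nb) + [(_TAU_FLOOR, 10.0)]
    res = minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-6})
    params = res.x
    tau = params[-1]
    tau2 = 0.0 if tau <= _TAU_FLOOR * (1 + 1e-9) else float(tau**2)
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
    return RandomFitOrdinal(
        thresholds=obj.thresholds(params[:M]),
        beta_hat=float(params[M]) if include_x else None,
        tau2_hat=tau2,
        loglik=float(-res.fun),
        converged=converged,
        n_quad=n_quad,
    )


def _fit_po_pooled(lev: np.ndarray, x: np.ndarray, M: int, include_x: bool):
    """Quick pooled (no hospital effects) proportional-odds Newton fit."""
    c = _start_thresholds(lev, M)
    beta = 0.0
    idx_hi = np.minimum(lev, M - 1)
    idx_lo = np.maximum(lev - 1, 0)
    has_hi = lev < M
    has_lo = lev > 0
    for _ in range(25):
        u = beta * x if include_x else np.zeros_like(x)
        ll, g_hi, g_lo, h_hihi, h_lolo, h_hilo = _po_row_derivs(lev, u, c)
        g_u = -(g_hi + g_lo)
        S = h_hihi + 2 * h_hilo + h_lolo
        P_dim = M + (1 if include_x else 0)
        grad = np.zeros(P_dim)
        np.add.at(grad, idx_hi, np.where(has_hi, g_hi, 0.0))
        np.add.at(grad, idx_lo, np.where(has_lo, g_lo, 0.0))
        H = np.zeros((P_dim, P_dim))
        np.add.at(H, (idx_hi, idx_hi), np.where(has_hi, h_hihi, 0.0))
        np.add.at(H, (idx_lo, idx_lo), np.where(has_lo, h_lolo, 0.0))
        both = has_hi & has_lo
        np.add.at(H, (idx_hi, idx_lo), np.where(both, h_hilo, 0.0))
        np.add.at(H, (idx_lo, idx_hi), np.where(both, h_hilo, 0.0))
        if include_x:
            grad[M] = float(g_u @ x)
            cu_hi = -(h_hihi + h_hilo)
            cu_lo = -(h_lolo + h_hilo)
            for m in range(M):
                w = np.where(has_hi & (idx_hi == m), cu_hi, 0.0) + np.where(
                    has_lo & (idx_lo == m), cu_lo, 0.0)
                H[m, M] += float(w @ x)
                H[M, m] = H[m, M]
            H[M, M] = float(S @ (x * x))
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ls in range(20):
            c_new = c + t * step[:M]
            if np.all(np.diff(c_new) > 0):
                break
            t /= 2
        c = c + t * step[:M]
        if include_x:
            beta += t * step[M]
        if np.max(np.abs(t * step)) < 1e-9:
            break
    return c, beta
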