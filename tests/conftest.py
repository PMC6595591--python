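"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the package's own quadrature/optimisation
code paths: marginal likelihoods are recomputed by dense trapezoid
integration over the random effect, and reference model fits come from
closed forms or statsmodels.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ranklab.synthetic_data import CalibrationResult, ScenarioA, ScenarioB
from ranklab import simulate_binary_dataset, simulate_composite_dataset


def dense_binary_marginal_ll(df, alpha0, beta, tau, indicator="y1", span=8.0, n_grid=4001):
    """Brute-force marginal log-likelihood of the random-intercept logistic model."""
    tau = max(tau, 1e-6)
    total = 0.0
    for _, grp in df.groupby("hospital_id"):
        y = grp[indicator].to_numpy(dtype=float)
        x = grp["x"].to_numpy()
        a = np.linspace(alpha0 - span * tau, alpha0 + span * tau, n_grid)
        eta = a[:, None] + (beta or 0.0) * x[None, :]
        ll = (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        dens = np.exp(ll) * np.exp(-((a - alpha0) ** 2) / (2 * tau**2)) / (tau * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(dens, a))
    return total


def dense_ordinal_marginal_ll(df, thresholds, beta, tau, span=8.0, n_grid=4001):
    """Brute-force marginal log-likelihood of the random-intercept PO model."""
    tau = max(tau, 1e-6)
    values = np.unique(df["y_ordinal"])
    M = values.size - 1
    c = np.asarray(thresholds, dtype=float)
    total = 0.0
    for _, grp in df.groupby("hospital_id"):
        lev = np.searchsorted(values, grp["y_ordinal"].to_numpy())
        x = grp["x"].to_numpy()
        a = np.linspace(-span * tau, span * tau, n_grid)
        u = (beta or 0.0) * x[None, :] + a[:, None]
        hi = np.where(lev[None, :] < M, expit(c[np.minimum(lev, M - 1)][None, :] - u), 1.0)
        lo = np.where(lev[None, :] > 0, expit(c[np.maximum(lev - 1, 0)][None, :] - u), 0.0)
        ll = np.log(np.clip(hi - lo, 1e-300, None)).sum(axis=1)
        dens = np.exp(ll) * np.exp(-(a**2) / (2 * tau**2)) / (tau * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(dens, a))
    return total


@pytest.fixture(scope="session")
def toy_binary():
    """5 hospitals x 20 patients, moderate clustering."""
    s = ScenarioA(icc=0.15, alpha0=-1.0, alpha1=0.25, n_hospitals=5, n_per_hospital=20)
    return simulate_binary_dataset(s, 12345)


@pytest.fixture(scope="session")
def toy_composite():
    """5 hospitals x 30 patients with correlated components and composite."""
    s = ScenarioB(re_correlation=0.75, n_hospitals=5, n_per_hospital=30)
    cal = CalibrationResult(
        alpha0=[-2.2, -1.6, -0.8],
        tau=[0.8, 0.8, 0.8],
        achieved_prevalences=[np.nan] * 3,
        achieved_rankabilities=[np.nan] * 3,
    )
    return simulate_composite_dataset(s, cal, 777)


@pytest.fixture(scope="session")
def medium_composite():
    """30 hospitals x 120 patients; all hospitals identifiable in fixed fits."""
    s = ScenarioB(
        prevalences=(0.15, 0.2, 0.3),
        re_correlation=0.5,
        n_hospitals=30,
        n_per_hospital=120,
    )
    cal = CalibrationResult(
        alpha0=[-1.9, -1.5, -0.95],
        tau=[0.5, 0.5, 0.5],
        achieved_prevalences=[np.nan] * 3,
        achieved_rankabilities=[np.nan] * 3,
    )
    return simulate_composite_dataset(s, cal, 4242)
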