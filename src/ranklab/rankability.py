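"""Rankability of hospital-performance indicators.

Rankability (also called statistical reliability) quantifies how much of
the observed between-hospital variation in an indicator reflects true
differences between hospitals rather than chance:

    rho = tau^2 / (tau^2 + median_j(s_j^2))

where ``tau^2`` is the between-hospital variance of a random-intercept
(logistic or cumulative-logit) model and ``s_j`` is the standard error of
hospital *j*'s effect in the companion fixed-effects model.  Values above
0.7 are conventionally read as "high" rankability, values below 0.5 as
"low" — an indicator with low rankability cannot support a meaningful
league table.

The closely related intraclass correlation (ICC, latent-variable variance
partition coefficient) for a multilevel logistic model is

    ICC = tau^2 / (tau^2 + pi^2 / 3)

with ``pi^2/3`` the variance of the standard logistic distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mixed_models

__all__ = [
    "RankabilityEstimate",
    "icc_latent",
    "rankability_from_components",
    "estimate_rankability",
    "rankability_band",
]

_LOGISTIC_VAR = np.pi**2 / 3.0


@dataclass(frozen=True)
class RankabilityEstimate:
    """Rankability of one indicator on one dataset, with its ingredients."""

    rho: float
    tau2_hat: float
    median_s2: float
    n_hospitals_used: int
    indicator: str
    converged: bool = True

    def __post_init__(self) -> None:
        expected = self.tau2_hat / (self.tau2_hat + self.median_s2)
        if not np.isclose(self.rho, expected, rtol=0, atol=1e-12):
            raise ValueError("rho inconsistent with tau2_hat and median_s2")


def icc_latent(tau2: float) -> float:
    """Latent-variable ICC of a random-intercept logistic model.

    Parameters
    ----------
    tau2
        Between-hospital variance of the random intercepts (logit^2 scale).
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be non-negative, got {tau2}")
    return tau2 / (tau2 + _LOGISTIC_VAR)


def rankability_from_components(tau2: float, ses: np.ndarray, indicator: str = "y1") -> RankabilityEstimate:
    """Combine a random-effects variance and fixed-effects standard errors.

    The standard errors are squared first; the median of the squared values
    is used (for an even number of hospitals, the mean of the central pair).
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be non-negative, got {tau2}")
    ses = np.asarray(ses, dtype=float)
    if ses.size == 0:
        raise ValueError("ses must be non-empty")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    median_s2 = float(np.median(ses**2))
    rho = tau2 / (tau2 + median_s2)
    return RankabilityEstimate(
        rho=float(rho),
        tau2_hat=float(tau2),
        median_s2=median_s2,
        n_hospitals_used=int(ses.size),
        indicator=indicator,
    )


def estimate_rankability(
    data: pd.DataFrame,
    indicator: str = "y1",
    include_x: bool = True,
    n_quad: int = 15,
) -> RankabilityEstimate:
    """Estimate rankability of one indicator from a clustered dataset.

    Fits the matching random-intercept model (for ``tau2_hat``) and
    fixed-effects model (for the per-hospital standard errors ``s_j``),
    then forms ``rho = tau2_hat / (tau2_hat + median(s_j^2))``.

    Parameters
    ----------
    data
        Long-format patient records with columns ``hospital_id``, ``x`` and
        the indicator column(s).
    indicator
        One of ``"y1"``, ``"y2"``, ``"y3"`` (binary) or ``"ordinal"`` for
        the five-level composite indicator in column ``y_ordinal``.
    include_x
        Whether to adjust for the patient risk score in both models.
    """
    if indicator == "ordinal":
        rfit = mixed_models.fit_ordinal_random(data, include_x=include_x, n_quad=n_quad)
        ffit = mixed_models.fit_ordinal_fixed(data, include_x=include_x)
    else:
        rfit = mixed_models.fit_logistic_random(data, indicator=indicator, include_x=include_x, n_quad=n_quad)
        ffit = mixed_models.fit_logistic_fixed(data, indicator=indicator, include_x=include_x)
    est = rankability_from_components(rfit.tau2_hat, ffit.hospital_ses, indicator=indicator)
    converged = bool(rfit.converged and ffit.converged)
    return RankabilityEstimate(
        rho=est.rho,
        tau2_hat=est.tau2_hat,
        median_s2=est.median_s2,
        n_hospitals_used=est.n_hospitals_used,
        indicator=indicator,
        converged=converged,
    )


def rankability_band(rho: float) -> str:
    """Label a rankability value as 'low' (<0.5), 'moderate' (0.5-0.7) or 'high' (>0.7)."""
    if not 0 <= rho <= 1:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if rho < 0.5:
        return "low"
    if rho <= 0.7:
        return "moderate"
    return "high"
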