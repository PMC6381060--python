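"""Psychometric fitting and aftereffect summaries.

The proportion of "upward" reports as a function of test direction θ is
fitted with a cumulative Gaussian with a shared lapse rate,

    ψ(θ) = γ + (1 - 2γ)·Φ((θ - μ)/σ),       γ ∈ [0, 0.25],

by maximum likelihood (binomial counts) or weighted least squares
(real-valued model probabilities).  μ is the point of subjective equality
(PSE): with equal asymptotes ψ(μ) = 0.5, the direction perceived as
horizontal.  Aftereffects are summarized by ΔPSE = PSE_USK − PSE_DSK (the
repulsive aftereffect magnitude) and ΣPSE = PSE_USK + PSE_DSK (the ordering
bias), and model variants are scored by the mean deviation of their
predictions from reference intervals (err_avg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "AftereffectSummary",
    "VariantEvaluation",
    "psychometric_fn",
    "fit_psychometric",
    "aftereffect_summary",
    "prediction_error",
]


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian fit; ``pse`` is μ, ``slope`` the Gaussian SD."""

    pse: float
    slope: float
    asymptote: float
    loglik: float
    converged: bool

    def predict(self, theta) -> np.ndarray:
        return psychometric_fn(np.asarray(theta, float), self.pse, self.slope, self.asymptote)


@dataclass(frozen=True)
class AftereffectSummary:
    pse_usk: float
    pse_dsk: float

    @property
    def delta_pse(self) -> float:
        return self.pse_usk - self.pse_dsk

    @property
    def sum_pse(self) -> float:
        return self.pse_usk + self.pse_dsk


@dataclass(frozen=True)
class VariantEvaluation:
    """Deviations of predictions from reference intervals and their mean."""

    deviations: dict
    err_avg: float


def psychometric_fn(theta, mu: float, sigma: float, gamma: float) -> np.ndarray:
    return gamma + (1.0 - 2.0 * gamma) * norm.cdf((theta - mu) / sigma)


def _neg_objective(params, theta, p, k, n, weights):
    mu, sigma, gamma = params
    psi = np.clip(psychometric_fn(theta, mu, sigma, gamma), 1e-9, 1.0 - 1e-9)
    if k is not None:
        return -float(np.sum(k * np.log(psi) + (n - k) * np.log(1.0 - psi)))
    return float(np.sum(weights * (p - psi) ** 2))


def fit_psychometric(
    theta,
    p_up=None,
    k=None,
    n=None,
    weights=None,
    sigma_min: float = 1e-3,
) -> PsychometricFit:
    """Fit ψ(θ) to upward-response data.

    Parameters
    ----------
    theta
        Test directions in degrees (≥ 4 distinct levels).
    p_up
        Real-valued response probabilities per entry (weighted least squares).
    k, n
        Alternatively, upward counts out of n trials per level (binomial
        maximum likelihood).
    weights
        Optional least-squares weights (default 1).

    Uses bounded L-BFGS-B from deterministic multi-starts
    (μ ∈ {min θ, 0, max θ} × σ ∈ {span/4, span/2}); the best objective wins,
    ties broken by the smallest |μ|.  Degenerate data (all responses 0 or
    all 1) are rejected.
    """
    theta = np.asarray(theta, dtype=float)
    if np.unique(theta).size < 4:
        raise ValueError("need at least 4 distinct test levels")
    if (p_up is None) == (k is None):
        raise ValueError("provide exactly one of p_up or (k, n)")
    if k is not None:
        if n is None:
            raise ValueError("binomial mode needs n")
        k = np.asarray(k, dtype=float)
        n = np.broadcast_to(np.asarray(n, dtype=float), k.shape)
        frac = k / n
    else:
        p_up = np.asarray(p_up, dtype=float)
        if np.any((p_up < 0) | (p_up > 1)):
            raise ValueError("responses must lie in [0, 1]")
        frac = p_up
        weights = np.ones_like(p_up) if weights is None else np.asarray(weights, float)
    if np.all(frac == 0.0) or np.all(frac == 1.0):
        raise ValueError("degenerate data: all responses identical at 0 or 1")

    span = float(theta.max() - theta.min())
    bounds = [
        (theta.min() - span, theta.max() + span),
        (sigma_min, 10.0 * span),
        (0.0, 0.25),
    ]
    starts = [
        (mu0, s0, 0.02)
        for mu0 in (float(theta.min()), 0.0, float(theta.max()))
        for s0 in (span / 4.0, span / 2.0)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_objective,
            x0,
            args=(theta, frac if k is None else None, k, n, weights),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        key = (round(res.fun, 12), abs(res.x[0]))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    mu, sigma, gamma = res.x
    return PsychometricFit(
        pse=float(mu),
        slope=float(sigma),
        asymptote=float(gamma),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )


def aftereffect_summary(
    fit_usk: PsychometricFit, fit_dsk: PsychometricFit
) -> AftereffectSummary:
    """ΔPSE and ΣPSE from the two adapting-condition fits."""
    if not (fit_usk.converged and fit_dsk.converged):
        raise ValueError("both psychometric fits must have converged")
    return AftereffectSummary(pse_usk=fit_usk.pse, pse_dsk=fit_dsk.pse)


def prediction_error(predictions: dict, reference_intervals: dict) -> VariantEvaluation:
    """Mean deviation of predictions from reference intervals (err_avg).

    ``predictions`` maps keys (e.g. (experiment, summary-name)) to values;
    ``reference_intervals`` maps the same keys to (lo, hi) pairs, where
    ``None`` stands for an unbounded side.  The deviation of a prediction is
    its distance outside its interval (0 inside); err_avg is the mean over
    all provided predictions.
    """
    devs = {}
    for key, p in predictions.items():
        lo, hi = reference_intervals[key]
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        if lo > hi:
            raise ValueError(f"malformed interval for {key}: ({lo}, {hi})")
        if not np.isfinite(p):
            raise ValueError(f"non-finite prediction for {key}")
        devs[key] = max(0.0, lo - p, p - hi)
    return VariantEvaluation(deviations=devs, err_avg=float(np.mean(list(devs.values()))))
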