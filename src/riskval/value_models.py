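"""Subjective-value models: EU, PT (Goldstein–Einhorn), and MVS.

All three models map a two-outcome lottery to a scalar subjective value:

* EU:  ``U = p x1^rho + (1-p) x2^rho`` with curvature ``rho > 0``.
* PT:  ``U = w(p) x1^rho + (1 - w(p)) x2^rho`` where
  ``w(p) = delta p^gamma / (delta p^gamma + (1-p)^gamma)`` distorts the
  probability of the *high* outcome (the low outcome gets ``1 - w(p)``, not
  ``w(1-p)``). Outcomes here are gains only, so no loss domain is modeled.
* MVS: ``U = beta_mu Mean + beta_sigma Variance + beta_gamma Skewness``
  over the lottery's distribution moments.

Utilities are converted to certainty equivalents (the sure amount with the
same model utility) so that values from different models live on a common
points scale; the Luce rule then maps a value difference to a choice
probability via a unit-temperature logistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import expit

from .lotteries import Lottery, LotteryError, moments, moments_arrays


class ParameterError(ValueError):
    """Raised when model parameters violate their sign constraints."""


@dataclass(frozen=True)
class EUParams:
    """Expected-utility parameters: power-utility curvature ``rho > 0``."""

    rho: float

    def __post_init__(self) -> None:
        if not (self.rho > 0 and math.isfinite(self.rho)):
            raise ParameterError(f"rho must be positive, got {self.rho}")


@dataclass(frozen=True)
class PTParams:
    """Prospect-theory parameters: curvature ``rho``, weighting elevation
    ``delta`` and weighting curvature ``gamma``, all strictly positive."""

    rho: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("rho", "delta", "gamma"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class MVSParams:
    """Mean-variance-skewness weights. ``beta_mu > 0`` (more is better);
    ``beta_sigma`` (< 0 means risk aversion) and ``beta_gamma`` are free."""

    beta_mu: float
    beta_sigma: float
    beta_gamma: float

    def __post_init__(self) -> None:
        if not (self.beta_mu > 0 and math.isfinite(self.beta_mu)):
            raise ParameterError(f"beta_mu must be positive, got {self.beta_mu}")
        for name in ("beta_sigma", "beta_gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")


Params = Union[EUParams, PTParams, MVSParams]

MODEL_NAMES = ("EU", "PT", "MVS")


def model_of(params: Params) -> str:
    if isinstance(params, EUParams):
        return "EU"
    if isinstance(params, PTParams):
        return "PT"
    if isinstance(params, MVSParams):
        return "MVS"
    raise ParameterError(f"unknown parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# Probability weighting
# ---------------------------------------------------------------------------


def weight_probability(p, delta: float, gamma: float):
    """Goldstein–Einhorn weighting ``w(p) = d p^g / (d p^g + (1-p)^g)``.

    ``delta`` shifts the curve up or down (elevation); ``gamma`` controls
    its inverse-S curvature. ``w(0) = 0`` and ``w(1) = 1`` for any positive
    parameters. Accepts scalars or arrays.
    """
    if delta <= 0 or gamma <= 0:
        raise ParameterError("delta and gamma must be positive")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)) or not np.all(np.isfinite(p_arr)):
        raise LotteryError("probabilities must lie in [0, 1]")
    # w = expit(log delta + gamma * logit(p)): stable for extreme delta/gamma
    interior = (p_arr > 0.0) & (p_arr < 1.0)
    w = np.where(p_arr == 1.0, 1.0, 0.0)
    with np.errstate(divide="ignore"):
        log_odds = math.log(delta) + gamma * (
            np.log(np.where(interior, p_arr, 0.5))
            - np.log1p(-np.where(interior, p_arr, 0.5))
        )
    w = np.where(interior, expit(log_odds), w)
    return float(w) if np.isscalar(p) or np.ndim(p) == 0 else w


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------


def _power(x, rho):
    """x**rho with 0**rho := 0 (continuous extension for rho > 0)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** rho
    return out


def utility_eu(lottery: Lottery, params: EUParams) -> float:
    """Expected power utility ``p x1^rho + (1-p) x2^rho``."""
    u = lottery.p * _power(np.array(lottery.x1), params.rho) + (
        1.0 - lottery.p
    ) * _power(np.array(lottery.x2), params.rho)
    return float(u)


def utility_pt(lottery: Lottery, params: PTParams) -> float:
    """PT utility with distorted decision weight on the high outcome."""
    w = weight_probability(lottery.p, params.delta, params.gamma)
    u = w * _power(np.array(lottery.x1), params.rho) + (1.0 - w) * _power(
        np.array(lottery.x2), params.rho
    )
    return float(u)


def utility_mvs(
    lottery: Lottery, params: MVSParams, *, standardized_skew: bool = True
) -> float:
    """Weighted sum of the lottery's mean, variance, and skewness."""
    m, v, s = moments(lottery, standardized=standardized_skew)
    return params.beta_mu * m + params.beta_sigma * v + params.beta_gamma * s


def utility(lottery: Lottery, params: Params) -> float:
    """Dispatch to the utility of the model matching ``params``."""
    if isinstance(params, EUParams):
        return utility_eu(lottery, params)
    if isinstance(params, PTParams):
        return utility_pt(lottery, params)
    return utility_mvs(lottery, params)


# ---------------------------------------------------------------------------
# Certainty equivalents
# ---------------------------------------------------------------------------


def certainty_equivalent(utility_value: float, params: Params):
    """Sure amount whose model utility equals ``utility_value``.

    EU/PT: ``CE = U**(1/rho)`` (a sure amount m has utility m^rho).
    MVS:   ``CE = U / beta_mu`` (a sure amount m has moments (m, 0, 0)).
    """
    if isinstance(params, (EUParams, PTParams)):
        if utility_value < 0:
            raise LotteryError("EU/PT utility of nonnegative outcomes cannot be negative")
        return utility_value ** (1.0 / params.rho)
    return utility_value / params.beta_mu


def _log_weighted_power_sum(x1, x2, w, rho):
    """log(w x1^rho + (1-w) x2^rho) computed stably for large rho."""
    with np.errstate(divide="ignore"):
        a = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf) + np.where(
            x1 > 0, rho * np.log(np.maximum(x1, 1e-300)), -np.inf
        )
        b = np.where(w < 1, np.log(np.maximum(1.0 - w, 1e-300)), -np.inf) + np.where(
            x2 > 0, rho * np.log(np.maximum(x2, 1e-300)), -np.inf
        )
    return np.logaddexp(a, b)


def lottery_ce(x1, x2, p, params: Params, *, standardized_skew: bool = True):
    """Certainty equivalents for arrays of lotteries under one parameter set.

    This is the numerically safe work-horse for likelihoods and neural
    modulators: EU/PT certainty equivalents are evaluated in log space so
    that extreme curvature exponents explored by the optimizer do not
    overflow.
    """
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if isinstance(params, EUParams):
        logu = _log_weighted_power_sum(x1, x2, p, params.rho)
        return np.where(np.isneginf(logu), 0.0, np.exp(logu / params.rho))
    if isinstance(params, PTParams):
        w = weight_probability(p, params.delta, params.gamma)
        logu = _log_weighted_power_sum(x1, x2, np.atleast_1d(w), params.rho)
        return np.where(np.isneginf(logu), 0.0, np.exp(logu / params.rho))
    m, v, s = moments_arrays(x1, x2, p, standardized=standardized_skew)
    u = params.beta_mu * m + params.beta_sigma * v + params.beta_gamma * s
    return u / params.beta_mu


def lottery_utility(x1, x2, p, params: Params, *, standardized_skew: bool = True):
    """Vectorized raw model utilities for arrays of lotteries.

    EU/PT utilities are evaluated through a log-space weighted power sum
    and the exponent capped (at 500 nats) so that extreme curvature values
    visited by the optimizer cannot overflow; the cap only bites where the
    logistic choice rule is already fully saturated.
    """
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if isinstance(params, EUParams):
        logu = _log_weighted_power_sum(x1, x2, p, params.rho)
        return np.where(np.isneginf(logu), 0.0, np.exp(np.minimum(logu, 500.0)))
    if isinstance(params, PTParams):
        w = weight_probability(p, params.delta, params.gamma)
        logu = _log_weighted_power_sum(x1, x2, np.atleast_1d(w), params.rho)
        return np.where(np.isneginf(logu), 0.0, np.exp(np.minimum(logu, 500.0)))
    m, v, s = moments_arrays(x1, x2, p, standardized=standardized_skew)
    return params.beta_mu * m + params.beta_sigma * v + params.beta_gamma * s


# ---------------------------------------------------------------------------
# Luce choice rule
# ---------------------------------------------------------------------------


def choice_probability(v_left, v_right):
    """Luce rule: ``P(left) = 1 / (1 + exp(V_R - V_L))``.

    A softmax over the two options with unit temperature; computed via a
    numerically stable logistic so large value differences saturate
    smoothly instead of overflowing.
    """
    v_left = np.asarray(v_left, dtype=float)
    v_right = np.asarray(v_right, dtype=float)
    if not (np.all(np.isfinite(v_left)) and np.all(np.isfinite(v_right))):
        raise LotteryError("subjective values must be finite")
    p = expit(v_left - v_right)
    return float(p) if p.ndim == 0 else p
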