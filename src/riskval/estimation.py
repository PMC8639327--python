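"""Maximum-likelihood fitting of EU/PT/MVS to choice data, AICc, BMS.

Each model is fitted per participant by maximizing the Luce-rule log
likelihood with Nelder–Mead from several random starting points.
Positivity-constrained parameters (rho, delta, gamma, beta_mu) are
optimized through the exponential transform ``psi = exp(theta)`` so the
search space is unconstrained; beta_sigma and beta_gamma are unconstrained
to begin with. The subjective values entering the choice rule are the raw
model utilities of the three value functions; this keeps all parameters
identifiable (on the certainty-equivalent scale the MVS weights enter only
through ratios). ``use_ce=True`` switches the likelihood to certainty
equivalents instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bms import BMSResult, EvidenceMatrix, rfx_bms
from .lotteries import LotteryError, TrialRecord
from .value_models import (
    EUParams,
    MVSParams,
    Params,
    PTParams,
    lottery_ce,
    lottery_utility,
    model_of,
)

MODEL_K = {"EU": 1, "PT": 3, "MVS": 3}

#: Start-value ranges for the multi-start optimizer. Positive parameters are
#: drawn log-uniformly; the sign-free MVS weights uniformly.
START_RANGES = {
    "rho": (0.2, 2.0),
    "delta": (0.2, 3.0),
    "gamma": (0.2, 2.0),
    "beta_mu": (0.05, 2.0),
    "beta_sigma": (-0.1, 0.1),
    "beta_gamma": (-2.0, 2.0),
}

_LOG_CLIP = math.log(1e-12)


class EstimationError(ValueError):
    """Raised for invalid fitting inputs."""


@dataclass
class FitResult:
    """One participant x model maximum-likelihood fit."""

    model: Literal["EU", "PT", "MVS"]
    params: Params
    log_likelihood: float
    aicc: float
    k: int
    n: int
    n_starts: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": vars(self.params) | {},
            "log_likelihood": self.log_likelihood,
            "aicc": self.aicc,
            "k": self.k,
            "n": self.n,
            "n_starts": self.n_starts,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Trial arrays
# ---------------------------------------------------------------------------


def trials_to_arrays(trials: Sequence[TrialRecord]) -> dict[str, np.ndarray]:
    """Columnar view of the non-missed trials, for vectorized likelihoods."""
    kept = [t for t in trials if t.choice != "missed"]
    if not kept:
        raise EstimationError("no non-missed trials")
    return {
        "x1l": np.array([t.pair.left.x1 for t in kept]),
        "x2l": np.array([t.pair.left.x2 for t in kept]),
        "pl": np.array([t.pair.left.p for t in kept]),
        "x1r": np.array([t.pair.right.x1 for t in kept]),
        "x2r": np.array([t.pair.right.x2 for t in kept]),
        "pr": np.array([t.pair.right.p for t in kept]),
        "chose_left": np.array([t.choice == "left" for t in kept]),
        "rt": np.array([np.nan if t.rt is None else t.rt for t in kept]),
    }


def trial_values(arrays: dict[str, np.ndarray], params: Params, *, use_ce: bool = False):
    """Per-trial subjective values for both sides (raw utilities by default)."""
    fn = lottery_ce if use_ce else lottery_utility
    vl = fn(arrays["x1l"], arrays["x2l"], arrays["pl"], params)
    vr = fn(arrays["x1r"], arrays["x2r"], arrays["pr"], params)
    return vl, vr


def _ll_from_arrays(arrays: dict[str, np.ndarray], params: Params, use_ce: bool) -> float:
    vl, vr = trial_values(arrays, params, use_ce=use_ce)
    d = vl - vr
    # log P(left) = -log(1 + exp(-d)); clipped away from -inf under separation
    log_pl = -np.logaddexp(0.0, -d)
    log_pr = -np.logaddexp(0.0, d)
    log_p = np.where(arrays["chose_left"], log_pl, log_pr)
    return float(np.sum(np.maximum(log_p, _LOG_CLIP)))


def log_likelihood(
    trials: Sequence[TrialRecord], params: Params, *, use_ce: bool = False
) -> float:
    """Luce-rule log likelihood ``sum_t I_L ln P_L + (1 - I_L) ln P_R``.

    Missed trials are excluded. Probabilities are clipped at 1e-12 so the
    result stays finite even when one option is strictly dominant and always
    chosen (complete separation).
    """
    return _ll_from_arrays(trials_to_arrays(trials), params, use_ce)


# ---------------------------------------------------------------------------
# AICc and classification
# ---------------------------------------------------------------------------


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: ``-2 LL + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise EstimationError(f"AICc requires n > k + 1 (got n={n}, k={k})")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def classify_participant(
    aicc_eu: float, aicc_pt: float, aicc_mvs: float, margin: float = 2.0
) -> str:
    """Assign a behavioral type by the AICc rule-of-thumb.

    Model M wins iff both rival AICc values exceed AICc_M by more than the
    margin (2 by convention); otherwise the participant is unclassified.
    At most one model can win.
    """
    vals = {"EU": aicc_eu, "PT": aicc_pt, "MVS": aicc_mvs}
    if not all(math.isfinite(v) for v in vals.values()):
        raise EstimationError("AICc values must be finite")
    for name, v in vals.items():
        if all(other - v > margin for key, other in vals.items() if key != name):
            return name
    return "unclassified"


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _theta_to_params(model: str, theta: np.ndarray) -> Params:
    if model == "EU":
        return EUParams(math.exp(theta[0]))
    if model == "PT":
        return PTParams(math.exp(theta[0]), math.exp(theta[1]), math.exp(theta[2]))
    return MVSParams(math.exp(theta[0]), theta[1], theta[2])


def _params_to_theta(params: Params) -> np.ndarray:
    if isinstance(params, EUParams):
        return np.array([math.log(params.rho)])
    if isinstance(params, PTParams):
        return np.log([params.rho, params.delta, params.gamma])
    return np.array([math.log(params.beta_mu), params.beta_sigma, params.beta_gamma])


def _draw_start(model: str, rng: np.random.Generator) -> np.ndarray:
    def logu(lo, hi):
        return rng.uniform(math.log(lo), math.log(hi))

    if model == "EU":
        return np.array([logu(*START_RANGES["rho"])])
    if model == "PT":
        return np.array(
            [logu(*START_RANGES["rho"]), logu(*START_RANGES["delta"]), logu(*START_RANGES["gamma"])]
        )
    return np.array(
        [
            logu(*START_RANGES["beta_mu"]),
            rng.uniform(*START_RANGES["beta_sigma"]),
            rng.uniform(*START_RANGES["beta_gamma"]),
        ]
    )


def fit_model(
    trials: Sequence[TrialRecord],
    model: Literal["EU", "PT", "MVS"],
    n_starts: int = 10,
    seed: int = 0,
    *,
    use_ce: bool = False,
    x0: Params | None = None,
    min_trials: int = 20,
) -> FitResult:
    """Fit one model to one participant's choices by multi-start Nelder–Mead.

    Each start is drawn from documented plausible ranges; the best
    log-likelihood across starts is returned. Deterministic for a given
    seed. ``x0`` adds a user-supplied start (e.g. for refit checks).
    """
    if model not in MODEL_K:
        raise EstimationError(f"unknown model {model!r}")
    if n_starts < 1:
        raise EstimationError("n_starts must be >= 1")
    arrays = trials_to_arrays(trials)
    n = int(arrays["chose_left"].size)
    if n < min_trials:
        raise EstimationError(f"need at least {min_trials} non-missed trials, got {n}")
    rng = np.random.default_rng(seed)

    def neg_ll(theta: np.ndarray) -> float:
        try:
            params = _theta_to_params(model, theta)
        except (OverflowError, ValueError):
            return 1e12
        ll = _ll_from_arrays(arrays, params, use_ce)
        return -ll if math.isfinite(ll) else 1e12

    starts = [_draw_start(model, rng) for _ in range(n_starts)]
    if x0 is not None:
        starts.append(_params_to_theta(x0))
    best = None
    any_converged = False
    for theta0 in starts:
        res = minimize(
            neg_ll,
            theta0,
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 5000, "maxfev": 10000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = _theta_to_params(model, best.x)
    ll = -float(best.fun)
    k = MODEL_K[model]
    return FitResult(
        model=model,
        params=params,
        log_likelihood=ll,
        aicc=aicc(ll, k, n),
        k=k,
        n=n,
        n_starts=len(starts),
        converged=any_converged,
    )


def fit_all_models(
    trials: Sequence[TrialRecord], n_starts: int = 10, seed: int = 0, *, use_ce: bool = False
) -> dict[str, FitResult]:
    """Fit EU, PT, and MVS to the same participant; seeds are per-model."""
    return {
        m: fit_model(trials, m, n_starts=n_starts, seed=seed + i, use_ce=use_ce)
        for i, m in enumerate(("EU", "PT", "MVS"))
    }


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_choices(
    trials: Sequence[TrialRecord],
    params: Params,
    seed: int | None = 0,
    *,
    use_ce: bool = False,
) -> tuple[np.ndarray, float, int]:
    """Deterministic per-trial predictions and accuracy for one model.

    Predicts the side with the higher choice probability (left iff
    ``P_L > 0.5``). Exact ties are broken by a seeded coin flip and
    counted; accuracy is the fraction of non-missed trials where the
    prediction matches the observed choice. Returns
    ``(sides, accuracy, n_ties)``.
    """
    arrays = trials_to_arrays(trials)
    vl, vr = trial_values(arrays, params, use_ce=use_ce)
    d = vl - vr
    sides = np.where(d > 0, "left", "right").astype(object)
    ties = d == 0
    n_ties = int(np.sum(ties))
    if n_ties:
        rng = np.random.default_rng(seed)
        sides[ties] = np.where(rng.random(n_ties) < 0.5, "left", "right")
    observed = np.where(arrays["chose_left"], "left", "right")
    accuracy = float(np.mean(sides == observed))
    return sides, accuracy, n_ties


# ---------------------------------------------------------------------------
# Group-level Bayesian model comparison from AICc
# ---------------------------------------------------------------------------


def behavioral_bms(
    aicc_table: pd.DataFrame | np.ndarray,
    models: Sequence[str] = ("EU", "PT", "MVS"),
    *,
    n_samples: int = 1_000_000,
    seed: int | None = 0,
) -> BMSResult:
    """Random-effects BMS on an AICc matrix (subjects x models).

    AICc is converted to an approximate log model evidence
    ``L = -AICc / 2`` and passed to :func:`riskval.bms.rfx_bms`. Only
    evidence differences within a subject matter, so any row-constant
    offset in AICc is irrelevant.
    """
    if isinstance(aicc_table, pd.DataFrame):
        models = list(aicc_table.columns)
        arr = aicc_table.to_numpy(dtype=float)
    else:
        arr = np.asarray(aicc_table, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise EstimationError("AICc matrix contains missing or non-finite cells")
    ev = EvidenceMatrix(-arr / 2.0, models=list(models))
    return rfx_bms(ev, n_samples=n_samples, seed=seed)
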