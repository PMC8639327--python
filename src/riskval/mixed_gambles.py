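"""Loss aversion and mean-variance analysis of 50/50 mixed gambles.

Accept/reject decisions on gambles offering a gain ``g`` or a loss ``l``
with equal probability are fitted two ways: (i) a logistic regression of
acceptance on gain and loss magnitudes, from which the loss-aversion ratio
``lambda = -beta_loss / beta_gain`` follows (lambda > 1 means losses weigh
more than gains); and (ii) a logistic regression on the gamble's expected
value ``(g - l)/2`` and variance ``((g + l)/2)^2`` (skewness is constant at
the fixed 0.5 probability, so it cannot be assessed). Across a
heterogeneous population the fitted lambda and variance weight are
negatively correlated: the more loss averse an agent, the more variance
appears aversive under the mean-variance description.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import spearmanr


class MixedGambleError(ValueError):
    pass


@dataclass(frozen=True)
class MixedGamble:
    """A 50/50 gamble: gain ``gain`` or lose ``loss`` (both magnitudes > 0)."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if not (self.gain > 0 and self.loss > 0):
            raise MixedGambleError("gain and loss magnitudes must be positive")

    @property
    def ev(self) -> float:
        return 0.5 * (self.gain - self.loss)

    @property
    def variance(self) -> float:
        return (0.5 * (self.gain + self.loss)) ** 2


@dataclass(frozen=True)
class AcceptTrial:
    """One accept/reject decision on a mixed gamble."""

    gamble: MixedGamble
    accepted: bool


@dataclass
class MixedFit:
    """Per-participant fits of the loss-aversion and mean-variance models."""

    beta_gain: float
    beta_loss: float
    lam: float
    beta_mu: float
    beta_sigma: float
    intercept: float = 0.0
    mv_intercept: float = 0.0
    lambda_defined: bool = True
    separated: bool = False


DEFAULT_GAINS = tuple(range(10, 41, 2))
DEFAULT_LOSSES = tuple(range(5, 21))


def _arrays(trials: Sequence[AcceptTrial]):
    g = np.array([t.gamble.gain for t in trials], dtype=float)
    l = np.array([t.gamble.loss for t in trials], dtype=float)
    y = np.array([t.accepted for t in trials], dtype=float)
    return g, l, y


def _logit_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Logistic ML fit; returns (coefficients, separated flag)."""
    Xc = sm.add_constant(X, has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            coefs = np.asarray(res.params)
            if not res.mle_retvals.get("converged", True) or np.max(np.abs(coefs)) > 50:
                separated = True
        except Exception:
            # complete separation: fall back to a ridge-stabilized fit
            res = sm.Logit(y, Xc).fit_regularized(alpha=1e-4, disp=0)
            coefs = np.asarray(res.params)
            separated = True
    return coefs, separated


def fit_loss_aversion(trials: Sequence[AcceptTrial], min_trials: int = 30) -> MixedFit:
    """Logistic fit of acceptance on gain and loss magnitudes.

    With gains coded positively and loss magnitudes positively, acceptance
    should rise with gain (beta_gain > 0) and fall with loss
    (beta_loss < 0); the loss-aversion ratio is
    ``lambda = -beta_loss / beta_gain``. lambda is flagged undefined when
    beta_gain <= 0. The mean-variance coefficients in the returned
    :class:`MixedFit` are filled by :func:`fit_mean_variance`.
    """
    if len(trials) < min_trials:
        raise MixedGambleError(f"need at least {min_trials} trials")
    g, l, y = _arrays(trials)
    if y.min() == y.max():
        raise MixedGambleError("need both accepts and rejects")
    coefs, separated = _logit_fit(np.column_stack([g, l]), y)
    _, beta_gain, beta_loss = coefs
    defined = beta_gain > 0 and beta_loss < 0
    lam = -beta_loss / beta_gain if beta_gain > 0 else float("nan")
    mv0, mu, sig = _fit_mean_variance_coefs(trials)
    return MixedFit(
        beta_gain=float(beta_gain),
        beta_loss=float(beta_loss),
        lam=float(lam),
        beta_mu=mu,
        beta_sigma=sig,
        intercept=float(coefs[0]),
        mv_intercept=mv0,
        lambda_defined=bool(defined),
        separated=separated,
    )


def _fit_mean_variance_coefs(trials: Sequence[AcceptTrial]) -> tuple[float, float, float]:
    g, l, y = _arrays(trials)
    ev = 0.5 * (g - l)
    var = (0.5 * (g + l)) ** 2
    coefs, _ = _logit_fit(np.column_stack([ev, var]), y)
    return float(coefs[0]), float(coefs[1]), float(coefs[2])


def fit_mean_variance(trials: Sequence[AcceptTrial], min_trials: int = 30) -> tuple[float, float]:
    """Logistic fit of acceptance on the gamble's EV and variance."""
    if len(trials) < min_trials:
        raise MixedGambleError(f"need at least {min_trials} trials")
    g, l, y = _arrays(trials)
    if y.min() == y.max():
        raise MixedGambleError("need both accepts and rejects")
    _, mu, sig = _fit_mean_variance_coefs(trials)
    return mu, sig


def fit_eu_mixed(trials: Sequence[AcceptTrial]) -> tuple[float, float]:
    """EU fit for mixed gambles: ``U = 0.5 g^rho - 0.5 l^rho``, Luce rule.

    Acceptance probability is ``logistic(U)`` (reject has value 0).
    Returns ``(rho, log_likelihood)``.
    """
    g, l, y = _arrays(trials)

    def nll(log_rho: float) -> float:
        rho = math.exp(log_rho)
        with np.errstate(over="ignore"):
            u = 0.5 * g**rho - 0.5 * l**rho
        u = np.clip(u, -700, 700)
        p = np.clip(expit(u), 1e-12, 1 - 1e-12)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    res = minimize_scalar(nll, bounds=(-3.0, 1.5), method="bounded")
    return math.exp(res.x), -res.fun


def predict_accept(trials: Sequence[AcceptTrial], fit: MixedFit, model: str = "loss_aversion"):
    """Predicted accept/reject per gamble (accept iff fitted P > 0.5)."""
    g, l, _ = _arrays(trials)
    if model == "loss_aversion":
        score = fit.intercept + fit.beta_gain * g + fit.beta_loss * l
    elif model == "mean_variance":
        score = (
            fit.mv_intercept
            + fit.beta_mu * 0.5 * (g - l)
            + fit.beta_sigma * (0.5 * (g + l)) ** 2
        )
    else:
        raise MixedGambleError(f"unknown model {model!r}")
    return score > 0  # logistic link: P > 0.5 iff the linear score is positive


def lambda_variance_correlation(fits: Sequence[MixedFit]) -> tuple[float, float, int]:
    """Spearman correlation across participants between lambda and beta_sigma.

    Participants with an undefined lambda are excluded; the count of
    exclusions is returned as the third element. A strongly negative
    correlation reproduces the behavioral link between loss aversion and
    variance aversion.
    """
    lam = np.array([f.lam for f in fits if f.lambda_defined])
    sig = np.array([f.beta_sigma for f in fits if f.lambda_defined])
    n_excluded = len(fits) - lam.size
    if lam.size < 10:
        raise MixedGambleError("need at least 10 participants with defined lambda")
    if np.ptp(lam) == 0 or np.ptp(sig) == 0:
        warnings.warn("degenerate correlation: a vector is constant")
        return float("nan"), float("nan"), n_excluded
    res = spearmanr(lam, sig)
    return float(res.statistic), float(res.pvalue), n_excluded


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def trials_to_frame(
    trials_per_participant: dict[str, Sequence[AcceptTrial]]
) -> pd.DataFrame:
    rows = [
        {"participant": pid, "gain": t.gamble.gain, "loss": t.gamble.loss,
         "accepted": int(t.accepted)}
        for pid, trials in trials_per_participant.items()
        for t in trials
    ]
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> dict[str, list[AcceptTrial]]:
    out: dict[str, list[AcceptTrial]] = {}
    for pid, sub in frame.groupby("participant"):
        out[str(pid)] = [
            AcceptTrial(MixedGamble(r.gain, r.loss), bool(r.accepted))
            for r in sub.itertuples()
        ]
    return out
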