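"""Random-effects Bayesian model selection (BMS) over log evidences.

Given a subjects-by-models matrix of log model evidences, random-effects
BMS treats the generating model as a random variable across subjects with
unknown population frequencies ``r ~ Dirichlet(alpha)``. A variational
fixed-point iteration estimates the Dirichlet counts; from them follow the
expected model frequencies ``r_k = alpha_k / sum(alpha)`` (the probability
that the model generated a randomly selected subject's data) and the
exceedance probabilities ``phi_k = P(r_k > r_j for all j)`` (the confidence
that model k is the most frequent one), estimated by Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma


@dataclass
class EvidenceMatrix:
    """Per-subject, per-model log evidences (nats)."""

    L: np.ndarray
    models: list[str] = field(default_factory=list)
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("evidence matrix must be 2-D (subjects x models)")
        n, k = self.L.shape
        if k < 2:
            raise ValueError("need at least two models")
        if n < 1:
            raise ValueError("need at least one subject")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("log evidences must be finite")
        if not self.models:
            self.models = [f"model{j}" for j in range(k)]
        if not self.subjects:
            self.subjects = [f"sub{j}" for j in range(n)]
        if len(self.models) != k or len(self.subjects) != n:
            raise ValueError("label lengths do not match the matrix")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EvidenceMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.columns), [str(i) for i in frame.index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.L, index=self.subjects, columns=self.models)


@dataclass
class BMSResult:
    """Dirichlet counts, expected frequencies, and exceedance probabilities."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray | None
    models: list[str]
    n_iterations: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        data = {"alpha": self.alpha, "expected_freq": self.expected_freq}
        if self.exceedance is not None:
            data["exceedance"] = self.exceedance
        return pd.DataFrame(data, index=self.models)


def rfx_bms(
    evidence: EvidenceMatrix | np.ndarray,
    alpha0: float | Sequence[float] = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    *,
    n_samples: int = 1_000_000,
    seed: int | None = 0,
    compute_exceedance: bool = True,
) -> BMSResult:
    """Variational random-effects BMS on a log-evidence matrix.

    The fixed point iterates responsibilities
    ``g_nk ∝ exp(L_nk + psi(alpha_k) - psi(sum alpha))`` (rows shifted by
    their max before exponentiation, so adding a constant to one subject's
    evidences changes nothing) and counts ``alpha_k = alpha0_k + sum_n g_nk``
    until the largest change in alpha falls below ``tol``.
    """
    if not isinstance(evidence, EvidenceMatrix):
        evidence = EvidenceMatrix(np.asarray(evidence, dtype=float))
    L = evidence.L - evidence.L.max(axis=1, keepdims=True)
    n, k = L.shape
    alpha0_vec = np.broadcast_to(np.asarray(alpha0, dtype=float), (k,)).copy()
    if np.any(alpha0_vec <= 0):
        raise ValueError("prior counts must be positive")
    alpha = alpha0_vec.copy() + float(n) / k
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0_vec + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    r = alpha / alpha.sum()
    phi = None
    if compute_exceedance:
        phi = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)
    return BMSResult(alpha, r, phi, list(evidence.models), it, converged)


def exceedance_probabilities(
    alpha: Sequence[float], n_samples: int = 1_000_000, seed: int | None = 0
) -> np.ndarray:
    """Monte Carlo ``phi_k = P(r_k > r_j for all j != k)`` under Dirichlet(alpha).

    Each draw assigns exactly one winner (argmax; exact ties — a
    probability-zero event — go to the lowest index), so the estimates sum
    to one. With fewer than 1e4 samples precision is poor and a warning is
    issued.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet counts must be positive")
    if n_samples < 10_000:
        warnings.warn("fewer than 1e4 Monte Carlo samples: exceedance estimates are noisy")
    rng = np.random.default_rng(seed)
    k = alpha.size
    counts = np.zeros(k, dtype=np.int64)
    remaining = int(n_samples)
    # draw in blocks to bound memory
    block = 200_000
    while remaining > 0:
        m = min(block, remaining)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        counts += np.bincount(winners, minlength=k)
        remaining -= m
    return counts / float(n_samples)
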