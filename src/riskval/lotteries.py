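"""Binary lotteries, lottery pairs, and observed choice trials.

A lottery ``x = (x1, p; x2, 1-p)`` pays ``x1`` points with probability ``p``
and ``x2`` points otherwise (1 point = 0.25 CHF). All outcomes are
nonnegative; the task battery draws magnitudes and probabilities from fixed
discrete sets spanning a wide range of variance and skewness so that the
three valuation models can, in principle, be told apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

#: Outcome magnitudes (points) used in the scanner task.
DEFAULT_MAGNITUDES: tuple[float, ...] = (
    0, 5, 7, 10, 12, 13, 15, 16, 17, 18, 19, 20, 22, 25, 27,
    30, 33, 35, 36, 38, 40, 42, 43, 47, 50,
)

#: Probabilities of the high outcome used in the scanner task.
DEFAULT_PROBABILITIES: tuple[float, ...] = (
    0, 0.05, 0.1, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5,
    0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1,
)

#: Conversion of task points to Swiss Francs.
CHF_PER_POINT = 0.25

#: Response window in seconds.
RESPONSE_WINDOW = 5.0


class LotteryError(ValueError):
    """Raised when a lottery, pair, or trial violates its invariants."""


@dataclass(frozen=True)
class Lottery:
    """A two-outcome gamble ``(x1, p; x2, 1-p)`` with ``x1 >= x2 >= 0``.

    A degenerate lottery with ``x1 == x2`` and ``0 < p < 1`` is normalized
    to a sure outcome (``p = 1``) at construction, so that skewness (which
    would be 0/0) is well defined downstream.
    """

    x1: float
    x2: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0) or not math.isfinite(self.p):
            raise LotteryError(f"probability must lie in [0, 1], got {self.p}")
        if self.x2 < 0 or self.x1 < self.x2 or not math.isfinite(self.x1):
            raise LotteryError(
                f"outcomes must satisfy x1 >= x2 >= 0, got ({self.x1}, {self.x2})"
            )
        if self.x1 == self.x2 and 0.0 < self.p < 1.0:
            object.__setattr__(self, "p", 1.0)  # normalize sure lottery

    @property
    def is_sure(self) -> bool:
        return self.p in (0.0, 1.0) or self.x1 == self.x2

    @property
    def sure_amount(self) -> float:
        if not self.is_sure:
            raise LotteryError("lottery is not degenerate")
        return self.x1 if self.p == 1.0 else self.x2


@dataclass(frozen=True)
class LotteryPair:
    """Two lotteries presented side by side on one trial."""

    left: Lottery
    right: Lottery


@dataclass(frozen=True)
class TrialRecord:
    """One observed decision: the pair shown, the side chosen, and the RT.

    ``choice`` is ``"left"``, ``"right"``, or ``"missed"``; the response
    time is absent exactly when the trial was missed and otherwise lies in
    the 5-s response window.
    """

    pair: LotteryPair
    choice: Literal["left", "right", "missed"]
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.choice not in ("left", "right", "missed"):
            raise LotteryError(f"invalid choice {self.choice!r}")
        if self.choice == "missed":
            if self.rt is not None:
                raise LotteryError("missed trials carry no response time")
        else:
            if self.rt is None or not (0.0 <= self.rt <= RESPONSE_WINDOW):
                raise LotteryError(
                    f"response time must lie in [0, {RESPONSE_WINDOW}] s, got {self.rt}"
                )


def moments(
    lottery: Lottery, *, standardized: bool = True
) -> tuple[float, float, float]:
    """Mean, variance, and skewness of a two-outcome lottery.

    Skewness is by default the standardized third central moment,
    ``(1 - 2p) / sqrt(p (1 - p))``; for a sure outcome it is assigned 0
    (the standardized moment is undefined there). With
    ``standardized=False`` the raw third central moment
    ``p (1-p) (1-2p) (x1-x2)^3`` is returned instead.
    """
    x1, x2, p = lottery.x1, lottery.x2, lottery.p
    mean = p * x1 + (1.0 - p) * x2
    spread = x1 - x2
    variance = p * (1.0 - p) * spread * spread
    if variance == 0.0:
        return mean, 0.0, 0.0
    if standardized:
        skew = (1.0 - 2.0 * p) / math.sqrt(p * (1.0 - p))
    else:
        skew = p * (1.0 - p) * (1.0 - 2.0 * p) * spread**3
    return mean, variance, skew


def moments_arrays(
    x1: np.ndarray,
    x2: np.ndarray,
    p: np.ndarray,
    *,
    standardized: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`moments` over parallel outcome/probability arrays."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p = np.asarray(p, dtype=float)
    mean = p * x1 + (1.0 - p) * x2
    spread = x1 - x2
    variance = p * (1.0 - p) * spread**2
    nondeg = variance > 0.0
    skew = np.zeros_like(mean)
    if standardized:
        pq = np.where(nondeg, p * (1.0 - p), 1.0)
        skew = np.where(nondeg, (1.0 - 2.0 * p) / np.sqrt(pq), 0.0)
    else:
        skew = np.where(nondeg, p * (1.0 - p) * (1.0 - 2.0 * p) * spread**3, 0.0)
    return mean, variance, skew


# ---------------------------------------------------------------------------
# Battery construction
# ---------------------------------------------------------------------------


def _random_lottery(rng: np.random.Generator, mags: np.ndarray, probs: np.ndarray) -> Lottery:
    p = float(rng.choice(probs))
    hi, lo = np.sort(rng.choice(mags, size=2, replace=False))[::-1]
    return Lottery(float(hi), float(lo), p)


def build_battery(
    magnitude_set: Sequence[float] = DEFAULT_MAGNITUDES,
    probability_set: Sequence[float] = DEFAULT_PROBABILITIES,
    n_pairs: int = 180,
    seed: int = 0,
) -> list[LotteryPair]:
    """Draw ``n_pairs`` distinct lottery pairs from the stimulus sets.

    Pairs are sampled uniformly at random (deterministically for a given
    seed) with two constraints: no pair presents identical lotteries on
    both sides, and the battery as a whole covers positive and negative
    skew as well as above- and below-median variance. Use
    :func:`battery_coverage` for the coverage counts. The published pair
    tables can be loaded with :func:`read_trials`-style delimited files
    instead if the exact stimuli are in hand.
    """
    if n_pairs <= 0:
        raise LotteryError("n_pairs must be positive")
    mags = np.unique(np.asarray(magnitude_set, dtype=float))
    probs = np.unique(np.asarray(probability_set, dtype=float))
    if mags.size < 2:
        raise LotteryError("magnitude set must contain at least two values")
    if probs.size == 0:
        raise LotteryError("probability set must be non-empty")
    rng = np.random.default_rng(seed)
    pairs: list[LotteryPair] = []
    guard = 0
    while len(pairs) < n_pairs:
        guard += 1
        if guard > 1000 * n_pairs:
            raise LotteryError("could not form enough distinct pairs from the sets")
        left = _random_lottery(rng, mags, probs)
        right = _random_lottery(rng, mags, probs)
        if (left.x1, left.x2, left.p) == (right.x1, right.x2, right.p):
            continue
        pairs.append(LotteryPair(left, right))
    # enforce skew/variance coverage by resampling the tail if needed
    cov = battery_coverage(pairs)
    needs = [k for k in ("pos_skew", "neg_skew", "high_variance", "low_variance") if cov[k] == 0]
    attempts = 0
    while needs and attempts < 10000:
        attempts += 1
        cand = LotteryPair(
            _random_lottery(rng, mags, probs), _random_lottery(rng, mags, probs)
        )
        pairs[-1 - (attempts % max(1, n_pairs // 4))] = cand
        cov = battery_coverage(pairs)
        needs = [
            k for k in ("pos_skew", "neg_skew", "high_variance", "low_variance") if cov[k] == 0
        ]
    return pairs


def battery_coverage(pairs: Iterable[LotteryPair]) -> dict[str, int]:
    """Counts of lotteries by skew sign and variance half (coverage report)."""
    lotteries = [lot for pr in pairs for lot in (pr.left, pr.right)]
    stats = np.array([moments(lot) for lot in lotteries])
    variances = stats[:, 1]
    med = float(np.median(variances))
    return {
        "n_lotteries": len(lotteries),
        "pos_skew": int(np.sum(stats[:, 2] > 0)),
        "neg_skew": int(np.sum(stats[:, 2] < 0)),
        "sure": int(np.sum(variances == 0)),
        "high_variance": int(np.sum(variances > med)),
        "low_variance": int(np.sum((variances > 0) & (variances <= med))),
    }


# ---------------------------------------------------------------------------
# Trial-table I/O (delimited text)
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "trial",
    "x1_left", "x2_left", "p_left",
    "x1_right", "x2_right", "p_right",
    "choice", "rt",
]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the canonical delimited-text layout."""
    rows = []
    for i, t in enumerate(trials):
        rows.append(
            {
                "trial": i,
                "x1_left": t.pair.left.x1,
                "x2_left": t.pair.left.x2,
                "p_left": t.pair.left.p,
                "x1_right": t.pair.right.x1,
                "x2_right": t.pair.right.x2,
                "p_right": t.pair.right.p,
                "choice": t.choice,
                "rt": np.nan if t.rt is None else t.rt,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild trial records from a table produced by :func:`trials_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        pair = LotteryPair(
            Lottery(row["x1_left"], row["x2_left"], row["p_left"]),
            Lottery(row["x1_right"], row["x2_right"], row["p_right"]),
        )
        rt = row["rt"]
        rt = None if pd.isna(rt) else float(rt)
        out.append(TrialRecord(pair, str(row["choice"]), rt))
    return out


def write_trials(trials: Sequence[TrialRecord], path, sep: str = ",") -> None:
    trials_to_frame(trials).to_csv(path, sep=sep, index=False)


def read_trials(path, sep: str = ",") -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path, sep=sep))
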