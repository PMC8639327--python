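"""Prediction-similarity analysis across the three valuation models.

Models that fit behavior comparably well often predict nearly the same
choices. This module quantifies that overlap: per-model predictive
accuracy, pairwise and three-way agreement of predicted choices, Spearman
correlations between the models' subjective values (on the cardinal
certainty-equivalent scale and on within-participant ordinal ranks), and
the correlation between response times and the absolute value difference
of the two options (harder choices take longer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .estimation import predict_choices, trial_values, trials_to_arrays
from .lotteries import Lottery, TrialRecord
from .value_models import Params, lottery_ce

MODEL_PAIRS = [("EU", "PT"), ("EU", "MVS"), ("PT", "MVS")]


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityReport:
    """Summary of how interchangeable the three models' predictions are."""

    accuracy: dict[str, float] = field(default_factory=dict)
    pairwise_agreement: dict[tuple[str, str], float] = field(default_factory=dict)
    three_way_agreement: float = float("nan")
    cardinal_rho: dict[tuple[str, str], float] = field(default_factory=dict)
    ordinal_rho: dict[tuple[str, str], float] = field(default_factory=dict)
    rt_rho: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair in MODEL_PAIRS:
            rows.append(
                {
                    "pair": "/".join(pair),
                    "agreement": self.pairwise_agreement.get(pair, np.nan),
                    "cardinal_rho": self.cardinal_rho.get(pair, np.nan),
                    "ordinal_rho": self.ordinal_rho.get(pair, np.nan),
                }
            )
        return pd.DataFrame(rows)


def pairwise_agreement(preds_a: Sequence, preds_b: Sequence) -> float:
    """Fraction of trials on which two models predict the same side,
    irrespective of whether the prediction is correct."""
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    if a.shape != b.shape or a.size == 0:
        raise SimilarityError("prediction vectors must be non-empty and equal length")
    return float(np.mean(a == b))


def joint_agreement(predictions: Sequence[Sequence]) -> float:
    """Fraction of trials on which *all* given models predict the same side."""
    arrs = [np.asarray(p) for p in predictions]
    if len(arrs) < 2:
        raise SimilarityError("need at least two prediction vectors")
    if len({a.shape for a in arrs}) != 1 or arrs[0].size == 0:
        raise SimilarityError("prediction vectors must be non-empty and equal length")
    same = np.ones(arrs[0].shape, dtype=bool)
    for a in arrs[1:]:
        same &= a == arrs[0]
    return float(np.mean(same))


def _battery_values(battery: Sequence[Lottery], params: Params, use_ce: bool) -> np.ndarray:
    x1 = np.array([lot.x1 for lot in battery])
    x2 = np.array([lot.x2 for lot in battery])
    p = np.array([lot.p for lot in battery])
    vals = lottery_ce(x1, x2, p, params)
    if not use_ce:
        from .value_models import utility

        vals = np.array([utility(lot, params) for lot in battery])
    return vals


def value_correlations(
    params_per_model: Mapping[str, Sequence[Params]],
    battery: Sequence[Lottery],
    scale: str = "cardinal",
    *,
    pooled: bool = True,
    use_ce: bool = True,
) -> dict[tuple[str, str], float]:
    """Spearman correlation of subjective values between model pairs.

    ``params_per_model`` maps a model name to one parameter set per
    participant. Cardinal values are certainty equivalents of every lottery
    in the battery; ordinal values replace them with within-participant
    ascending ranks (average ranks on ties). With ``pooled=True``
    (default) participant-by-lottery values are concatenated before
    correlating — the mode in which the cardinal/ordinal distinction is
    informative, because ranking removes between-participant scale
    differences. With ``pooled=False`` the per-participant correlations
    are averaged instead.
    """
    if scale not in ("cardinal", "ordinal"):
        raise SimilarityError(f"unknown scale {scale!r}")
    models = list(params_per_model)
    n_sub = {m: len(params_per_model[m]) for m in models}
    if len(set(n_sub.values())) != 1:
        raise SimilarityError("all models need the same number of participants")
    values = {
        m: np.array([_battery_values(battery, pp, use_ce) for pp in params_per_model[m]])
        for m in models
    }  # (participants, lotteries)
    for m, v in values.items():
        if np.any(np.ptp(v, axis=1) == 0):
            import warnings

            warnings.warn(f"constant value vector for model {m}: correlation undefined there")
    if scale == "ordinal":
        values = {m: np.apply_along_axis(rankdata, 1, v) for m, v in values.items()}
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(models, 2):
        if pooled:
            rho = spearmanr(values[a].ravel(), values[b].ravel()).statistic
        else:
            rhos = [
                spearmanr(values[a][i], values[b][i]).statistic
                for i in range(values[a].shape[0])
            ]
            rho = float(np.nanmean(rhos))
        out[(a, b)] = float(rho)
    return out


def rt_value_difference_correlation(
    trials: Sequence[TrialRecord], params: Params, *, use_ce: bool = True
) -> tuple[float, float]:
    """Spearman correlation between |V_L - V_R| and response time.

    Returns ``(rho, p_value)`` over the non-missed trials. Negative values
    indicate that closer-valued (harder) choices take longer.
    """
    arrays = trials_to_arrays(trials)
    ok = np.isfinite(arrays["rt"])
    if int(ok.sum()) < 10:
        raise SimilarityError("need at least 10 non-missed trials with RTs")
    vl, vr = trial_values(arrays, params, use_ce=use_ce)
    dv = np.abs(vl - vr)[ok]
    rt = arrays["rt"][ok]
    if np.ptp(rt) == 0:
        import warnings

        warnings.warn("all response times identical: correlation undefined")
        return float("nan"), float("nan")
    res = spearmanr(dv, rt)
    return float(res.statistic), float(res.pvalue)


def similarity_report(
    fits_per_model: Mapping[str, Sequence[Params]],
    trials_per_participant: Sequence[Sequence[TrialRecord]],
    battery: Sequence[Lottery],
    *,
    seed: int = 0,
) -> SimilarityReport:
    """Full similarity summary over a fitted population.

    Accuracies, agreements, and RT correlations are computed per
    participant on their own trials and averaged; value correlations pool
    participants over the supplied lottery battery.
    """
    models = list(fits_per_model)
    report = SimilarityReport()
    acc: dict[str, list[float]] = {m: [] for m in models}
    agree: dict[tuple[str, str], list[float]] = {p: [] for p in combinations(models, 2)}
    three: list[float] = []
    rt_rho: dict[str, list[float]] = {m: [] for m in models}
    for i, trials in enumerate(trials_per_participant):
        preds = {}
        for m in models:
            params = fits_per_model[m][i]
            sides, accuracy, _ = predict_choices(trials, params, seed=seed + i)
            preds[m] = sides
            acc[m].append(accuracy)
            rho, _ = rt_value_difference_correlation(trials, params)
            rt_rho[m].append(rho)
        for pair in agree:
            agree[pair].append(pairwise_agreement(preds[pair[0]], preds[pair[1]]))
        three.append(joint_agreement([preds[m] for m in models]))
    report.accuracy = {m: float(np.mean(acc[m])) for m in models}
    report.pairwise_agreement = {p: float(np.mean(v)) for p, v in agree.items()}
    report.three_way_agreement = float(np.mean(three))
    report.rt_rho = {m: float(np.nanmean(rt_rho[m])) for m in models}
    report.cardinal_rho = value_correlations(fits_per_model, battery, "cardinal")
    report.ordinal_rho = value_correlations(fits_per_model, battery, "ordinal")
    return report
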