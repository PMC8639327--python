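"""Synthetic agents, choices, RTs, mixed-gamble populations, and ROI BOLD.

Every input of the analysis pipeline can be generated here with documented
distributions and seeds, emulating the structure of the scanner study: 27
participants, 180 binary-lottery trials spread over 3 runs plus 45
null-fixation trials of 5.5 s, a 5-s response window, TR = 2.5 s.

Agents value lotteries with one of the three models (parameters drawn from
the documented population distributions below), choose stochastically via
the unit-temperature Luce rule, and respond faster the larger the absolute
certainty-equivalent difference between the options. ROI BOLD is generated
from the HRF-convolved, mean-centered state-value and value-difference
regressors of a designated true model plus AR(1) Gaussian noise.
All generators are pure functions of their seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lotteries import Lottery, LotteryPair, TrialRecord
from .mixed_gambles import (
    DEFAULT_GAINS,
    DEFAULT_LOSSES,
    AcceptTrial,
    MixedGamble,
)
from .neural_glm import ROITimeSeries, build_design_matrix, validate_events
from .value_models import (
    EUParams,
    MVSParams,
    Params,
    PTParams,
    lottery_ce,
    lottery_utility,
)

#: Population distributions for agent parameters (implementation choices for
#: recovery testing, spanning the empirically plausible ranges).
PARAM_DISTRIBUTIONS = {
    "rho": ("lognormal", math.log(0.85), 0.25),
    "delta": ("lognormal", math.log(0.9), 0.3),
    "gamma": ("lognormal", math.log(0.7), 0.3),
    "beta_mu": ("lognormal", math.log(0.5), 0.3),
    "beta_sigma": ("normal", -0.02, 0.01),
    "beta_gamma": ("normal", 0.3, 0.3),
}


def _draw(name: str, rng: np.random.Generator) -> float:
    kind, a, b = PARAM_DISTRIBUTIONS[name]
    if kind == "lognormal":
        return float(rng.lognormal(a, b))
    return float(rng.normal(a, b))


def draw_params(model: str, rng: np.random.Generator) -> Params:
    """One agent's parameters drawn from the population distributions."""
    if model == "EU":
        return EUParams(_draw("rho", rng))
    if model == "PT":
        return PTParams(_draw("rho", rng), _draw("delta", rng), _draw("gamma", rng))
    if model == "MVS":
        return MVSParams(_draw("beta_mu", rng), _draw("beta_sigma", rng), _draw("beta_gamma", rng))
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class AgentSpec:
    """A simulated decision-maker: valuation model plus RT mechanism.

    RT is linear in the absolute certainty-equivalent difference,
    ``rt = rt_intercept - rt_slope * |dCE| + N(0, rt_noise_sd)``, truncated
    to (0.2, 5.0] s — the simplest mechanism producing the negative
    RT/value-difference correlation seen empirically.
    """

    model: Literal["EU", "PT", "MVS"]
    params: Params
    rt_intercept: float = 2.5
    rt_slope: float = 0.04
    rt_noise_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be nonnegative")


@dataclass(frozen=True)
class PopulationSpec:
    """A homogeneous-model population of heterogeneous agents."""

    model: Literal["EU", "PT", "MVS"]
    n_agents: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")


@dataclass(frozen=True)
class BoldSpec:
    """Generative settings for ROI BOLD.

    Effect sizes are in percent signal change (baseline 100) per standard
    deviation of the convolved modulator; noise_sd is the marginal standard
    deviation of the AR(1) noise in the same units.
    """

    true_model: Literal["EU", "PT", "MVS"]
    effect_state: float = 0.8
    effect_diff: float = 0.8
    noise_sd: float = 1.0
    ar1: float = 0.3
    tr: float = 2.5
    n_runs: int = 3

    def __post_init__(self) -> None:
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 coefficient must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Choices and RTs
# ---------------------------------------------------------------------------


def _pair_values(battery: Sequence[LotteryPair], params: Params, use_ce: bool):
    fn = lottery_ce if use_ce else lottery_utility
    x = lambda side, attr: np.array([getattr(getattr(p, side), attr) for p in battery])
    vl = fn(x("left", "x1"), x("left", "x2"), x("left", "p"), params)
    vr = fn(x("right", "x1"), x("right", "x2"), x("right", "p"), params)
    return vl, vr


def simulate_choices(
    agent: AgentSpec,
    battery: Sequence[LotteryPair],
    seed: int = 0,
    *,
    use_ce: bool = False,
    miss_rate: float = 0.0,
) -> list[TrialRecord]:
    """Stochastic choices and RTs for one agent over a battery.

    Choices are Bernoulli draws from the Luce probability on the agent's
    subjective values (raw utilities by default, matching the fitted
    likelihood); RTs follow the agent's linear-in-|dCE| rule. A nonzero
    ``miss_rate`` drops responses at random as missed trials.
    """
    rng = np.random.default_rng(seed)
    vl, vr = _pair_values(battery, agent.params, use_ce)
    from scipy.special import expit

    p_left = expit(vl - vr)
    chose_left = rng.random(len(battery)) < p_left
    # RT runs on the CE scale regardless of the likelihood's value scale
    cel, cer = _pair_values(battery, agent.params, True)
    rt = (
        agent.rt_intercept
        - agent.rt_slope * np.abs(cel - cer)
        + rng.normal(0.0, agent.rt_noise_sd, len(battery))
    )
    rt = np.clip(rt, 0.2, 5.0)
    missed = rng.random(len(battery)) < miss_rate
    out = []
    for i, pair in enumerate(battery):
        if missed[i]:
            out.append(TrialRecord(pair, "missed", None))
        else:
            out.append(TrialRecord(pair, "left" if chose_left[i] else "right", float(rt[i])))
    return out


def simulate_population(
    spec: PopulationSpec,
    battery: Sequence[LotteryPair],
    *,
    use_ce: bool = False,
    miss_rate: float = 0.0,
) -> tuple[list[list[TrialRecord]], list[AgentSpec]]:
    """Trials and ground-truth agents for a population of one model type."""
    rng = np.random.default_rng(spec.seed)
    agents = [AgentSpec(spec.model, draw_params(spec.model, rng)) for _ in range(spec.n_agents)]
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_agents)
    trials = [
        simulate_choices(agent, battery, int(s), use_ce=use_ce, miss_rate=miss_rate)
        for agent, s in zip(agents, child_seeds)
    ]
    return trials, agents


# ---------------------------------------------------------------------------
# Mixed-gamble (gain/loss) population
# ---------------------------------------------------------------------------


def simulate_mixed_population(
    n: int = 30,
    lambda_range: tuple[float, float] = (1.0, 4.0),
    gains: Sequence[float] = DEFAULT_GAINS,
    losses: Sequence[float] = DEFAULT_LOSSES,
    trials_per_agent: int | None = None,
    tau: float = 0.2,
    seed: int = 0,
) -> tuple[list[list[AcceptTrial]], np.ndarray]:
    """Loss-averse agents deciding on 50/50 mixed gambles.

    Agent i accepts with probability
    ``logistic(tau * (0.5 gain - 0.5 lambda_i loss))`` with loss-aversion
    ratios drawn log-uniformly over ``lambda_range`` and choice sensitivity
    ``tau``. By default each agent sees the full gain-by-loss grid once.
    Returns the trial tables and the true lambdas.
    """
    if not (0 < lambda_range[0] <= lambda_range[1]):
        raise ValueError("lambda_range must be within (0, inf)")
    rng = np.random.default_rng(seed)
    lams = np.exp(rng.uniform(math.log(lambda_range[0]), math.log(lambda_range[1]), size=n))
    grid = [MixedGamble(float(g), float(l)) for g in gains for l in losses]
    from scipy.special import expit

    populations = []
    for lam in lams:
        if trials_per_agent is None:
            gambles = list(grid)
        else:
            idx = rng.integers(0, len(grid), size=trials_per_agent)
            gambles = [grid[i] for i in idx]
        u = np.array([tau * (0.5 * g.gain - 0.5 * lam * g.loss) for g in gambles])
        accepted = rng.random(len(gambles)) < expit(u)
        populations.append([AcceptTrial(g, bool(a)) for g, a in zip(gambles, accepted)])
    return populations, lams


# ---------------------------------------------------------------------------
# Event schedules and ROI BOLD
# ---------------------------------------------------------------------------


def make_event_schedule(
    trials: Sequence[TrialRecord],
    n_runs: int = 3,
    n_nulls: int = 45,
    seed: int = 0,
    iti_range: tuple[float, float] = (1.0, 3.0),
    tr: float = 2.5,
) -> tuple[pd.DataFrame, int]:
    """Event timeline for a session: trials split evenly over runs.

    Valid trials occupy the 5-s response window (the regressor lasts until
    the response and the decision event fires at the response); null
    trials last 5.5 s; inter-trial intervals are uniform over
    ``iti_range``. Returns the events table (with a ``trial`` index column
    linking valid/decision rows to trials) and the per-run scan count that
    accommodates the longest run plus HRF decay.
    """
    rng = np.random.default_rng(seed)
    per_run = len(trials) // n_runs
    nulls_per_run = n_nulls // n_runs
    rows = []
    run_ends = []
    ti = 0
    for run in range(n_runs):
        kinds = ["trial"] * per_run + ["null"] * nulls_per_run
        rng.shuffle(kinds)
        t = 10.0  # settle-in period
        for kind in kinds:
            iti = rng.uniform(*iti_range)
            if kind == "null":
                rows.append(
                    {"onset": t, "duration": 0.0, "trial_type": "null_trial",
                     "state_value": np.nan, "value_difference": np.nan,
                     "run": run, "trial": -1}
                )
                t += 5.5 + iti
                continue
            tr_rec = trials[ti]
            if tr_rec.choice == "missed":
                rows.append(
                    {"onset": t, "duration": 5.0, "trial_type": "missed_trial",
                     "state_value": np.nan, "value_difference": np.nan,
                     "run": run, "trial": ti}
                )
            else:
                rows.append(
                    {"onset": t, "duration": tr_rec.rt, "trial_type": "valid_trial",
                     "state_value": np.nan, "value_difference": np.nan,
                     "run": run, "trial": ti}
                )
                rows.append(
                    {"onset": t + tr_rec.rt, "duration": 0.0, "trial_type": "decision",
                     "state_value": np.nan, "value_difference": np.nan,
                     "run": run, "trial": ti}
                )
            ti += 1
            t += 5.0 + iti
        run_ends.append(t + 20.0)  # allow the HRF to decay
    events = pd.DataFrame(rows).sort_values(["run", "onset"], kind="stable").reset_index(drop=True)
    n_scans = int(math.ceil(max(run_ends) / tr))
    return events, n_scans


def attach_values(
    events: pd.DataFrame, trials: Sequence[TrialRecord], params: Params
) -> pd.DataFrame:
    """Fill the modulator columns from one model's certainty equivalents.

    State value is ``CE_L + CE_R`` (valid and missed trials); value
    difference is ``|CE_L - CE_R|`` (decision events).
    """
    x = lambda side, attr: np.array([getattr(getattr(t.pair, side), attr) for t in trials])
    cel = lottery_ce(x("left", "x1"), x("left", "x2"), x("left", "p"), params)
    cer = lottery_ce(x("right", "x1"), x("right", "x2"), x("right", "p"), params)
    state = cel + cer
    diff = np.abs(cel - cer)
    ev = events.copy()
    idx = ev["trial"].to_numpy()
    is_state = ev["trial_type"].isin(["valid_trial", "missed_trial"]).to_numpy()
    is_diff = (ev["trial_type"] == "decision").to_numpy()
    ev.loc[is_state, "state_value"] = state[idx[is_state]]
    ev.loc[is_diff, "value_difference"] = diff[idx[is_diff]]
    return ev


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    if phi == 0.0:
        return rng.normal(0.0, sd, size=n)
    w = rng.normal(0.0, sd * math.sqrt(1 - phi**2), size=n)
    e0 = rng.normal(0.0, sd)  # stationary start
    e, _ = lfilter([1.0], [1.0, -phi], w, zi=np.array([phi * e0]))
    return e


def simulate_roi_bold(
    events: pd.DataFrame,
    spec: BoldSpec,
    n_scans: int,
    seed: int = 0,
    *,
    baseline: float = 100.0,
) -> ROITimeSeries:
    """ROI BOLD from the true model's modulators plus AR(1) noise.

    The events table must already carry the true model's state-value and
    value-difference columns (see :func:`attach_values`). Each convolved,
    mean-centered modulator column is standardized and scaled by its
    effect size (percent signal change per SD); noise is AR(1) with the
    given lag-1 coefficient and marginal SD, drawn independently per run.
    """
    validate_events(events, n_scans, spec.tr)
    design = build_design_matrix(events, n_scans, spec.tr)
    rng = np.random.default_rng(seed)
    total = design.X.shape[0]
    y = np.full(total, baseline)
    for key, effect in (("state_value", spec.effect_state), ("value_diff", spec.effect_diff)):
        cols = design.columns_matching(key)
        for j in range(cols.shape[1]):
            col = cols[:, j]
            sd = col.std()
            if sd > 0:
                y = y + effect * (col - col.mean()) / sd
    for run in np.unique(design.runs):
        idx = design.runs == run
        y[idx] += _ar1_noise(int(idx.sum()), spec.noise_sd, spec.ar1, rng)
    return ROITimeSeries(y, spec.tr, design.runs)


def simulate_roi_voxels(
    events: pd.DataFrame,
    spec: BoldSpec,
    n_scans: int,
    n_voxels: int,
    seed: int = 0,
    *,
    baseline: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-voxel ROI BOLD: shared modulator signal, independent noise.

    Returns ``(Y, runs)`` with ``Y`` of shape (n_voxels, scans). Averaging
    per-voxel log evidences over such an ROI is what washes out
    noise-driven evidence differences between models when no signal is
    present.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    voxel_seeds = rng.integers(0, 2**31 - 1, size=n_voxels)
    series = [
        simulate_roi_bold(events, spec, n_scans, int(s), baseline=baseline)
        for s in voxel_seeds
    ]
    return np.stack([ts.y for ts in series]), series[0].runs


def simulate_activation_maps(
    shape: tuple[int, int, int],
    active_block: tuple[slice, slice, slice] | None,
    effect: float,
    noise_sd: float,
    n_subjects: int = 27,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject contrast maps on a small 3-D grid with a planted block.

    Gaussian noise everywhere; voxels inside ``active_block`` (if given)
    additionally carry a constant effect. Used to exercise the group
    conjunction machinery at desk scale.
    """
    rng = np.random.default_rng(seed)
    maps = rng.normal(0.0, noise_sd, size=(n_subjects,) + tuple(shape))
    if active_block is not None:
        maps[(slice(None),) + tuple(active_block)] += effect
    return maps
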