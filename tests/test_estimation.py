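import math

import numpy as np
import pytest

from riskval import (
    EUParams,
    MVSParams,
    PTParams,
    aicc,
    classify_participant,
    fit_model,
    log_likelihood,
)
from riskval.estimation import (
    EstimationError,
    behavioral_bms,
    predict_choices,
    trials_to_arrays,
)
from riskval.lotteries import Lottery, LotteryPair, TrialRecord
from riskval.synthetic import AgentSpec, simulate_choices
from riskval.value_models import lottery_utility


def brute_force_ll(trials, params):
    """Independent per-trial loop: sum of log choice probabilities."""
    total = 0.0
    for t in trials:
        if t.choice == "missed":
            continue
        ul = float(lottery_utility(t.pair.left.x1, t.pair.left.x2, t.pair.left.p, params)[0])
        ur = float(lottery_utility(t.pair.right.x1, t.pair.right.x2, t.pair.right.p, params)[0])
        if t.choice == "left":
            p = 1.0 / (1.0 + math.exp(ur - ul))
        else:
            p = 1.0 / (1.0 + math.exp(ul - ur))
        total += math.log(max(p, 1e-12))
    return total


@pytest.fixture(scope="module")
def random_trials(battery):
    rng = np.random.default_rng(11)
    return [
        TrialRecord(pair, "left" if rng.random() < 0.5 else "right", float(rng.uniform(0.3, 4.5)))
        for pair in battery[:100]
    ]


class TestLogLikelihood:
    @pytest.mark.parametrize(
        "params",
        [EUParams(0.8), PTParams(0.9, 0.8, 0.7), MVSParams(0.5, -0.02, 0.3)],
    )
    def test_matches_per_trial_oracle(self, random_trials, params):
        assert log_likelihood(random_trials, params) == pytest.approx(
            brute_force_ll(random_trials, params), abs=1e-10
        )

    def test_indifference_everywhere(self):
        # 180 pairs with equal expected value; linear utility is indifferent
        pair = LotteryPair(Lottery(20, 0, 0.5), Lottery(10, 10, 1.0))
        trials = [TrialRecord(pair, "left", 1.0)] * 90 + [TrialRecord(pair, "right", 1.0)] * 90
        assert log_likelihood(trials, EUParams(1.0)) == pytest.approx(180 * math.log(0.5))

    def test_single_trial_value(self):
        pair = LotteryPair(Lottery(20, 0, 0.5), Lottery(9, 9, 1.0))
        t = TrialRecord(pair, "left", 1.0)
        # V_L - V_R = 1 under linear utility -> ln(0.73106)
        assert log_likelihood([t], EUParams(1.0)) == pytest.approx(math.log(1 / (1 + math.e**-1)))

    def test_missed_trials_excluded(self, random_trials):
        pair = random_trials[0].pair
        extended = random_trials + [TrialRecord(pair, "missed", None)]
        p = EUParams(0.8)
        assert log_likelihood(extended, p) == log_likelihood(random_trials, p)

    def test_empty_rejected(self):
        with pytest.raises(EstimationError):
            log_likelihood([], EUParams(1.0))

    def test_separation_stays_finite(self, battery):
        # dominant-option data: always choose left when left strictly dominates
        trials = [
            TrialRecord(LotteryPair(Lottery(50, 40, 0.9), Lottery(5, 0, 0.1)), "left", 1.0)
        ] * 50
        ll = log_likelihood(trials, MVSParams(5.0, 0.0, 0.0))
        assert np.isfinite(ll)


class TestAicc:
    def test_arithmetic_examples(self):
        assert aicc(-100.0, 3, 180) == pytest.approx(206.0 + 24 / 176)
        assert aicc(0.0, 1, 180) == pytest.approx(2 + 4 / 178)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-50.0, 2, 10**7) == pytest.approx(104.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(EstimationError):
            aicc(-10.0, 3, 4)


class TestClassification:
    @pytest.mark.parametrize(
        "vals,expected",
        [
            ((210, 200, 210), "PT"),
            ((200, 199, 201), "unclassified"),
            ((195, 210, 210), "EU"),
            ((210, 210, 195), "MVS"),
            ((200, 200, 200), "unclassified"),
        ],
    )
    def test_rule(self, vals, expected):
        assert classify_participant(*vals) == expected

    def test_single_winner_only(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            vals = rng.uniform(180, 220, size=3)
            wins = [
                classify_participant(*np.roll(vals, -i)) for i in range(3)
            ]
            assert sum(w != "unclassified" for w in wins) <= 3  # consistent rule
            assert classify_participant(*vals) in ("EU", "PT", "MVS", "unclassified")


class TestFitting:
    def test_refit_from_optimum_is_fixed_point(self, battery):
        agent = AgentSpec("EU", EUParams(0.85))
        trials = simulate_choices(agent, battery, seed=5)
        fit = fit_model(trials, "EU", n_starts=5, seed=6)
        refit = fit_model(trials, "EU", n_starts=1, seed=7, x0=fit.params)
        assert refit.log_likelihood >= fit.log_likelihood - 1e-6

    def test_deterministic_given_seed(self, battery):
        trials = simulate_choices(AgentSpec("PT", PTParams(0.9, 0.8, 0.7)), battery, seed=8)
        f1 = fit_model(trials, "PT", n_starts=3, seed=9)
        f2 = fit_model(trials, "PT", n_starts=3, seed=9)
        assert f1.params == f2.params and f1.log_likelihood == f2.log_likelihood

    def test_guard_on_few_trials(self, battery):
        trials = simulate_choices(AgentSpec("EU", EUParams(0.9)), battery[:10], seed=1)
        with pytest.raises(EstimationError):
            fit_model(trials, "EU")

    def test_monotone_dominant_data_reported(self):
        # one option strictly dominant and always chosen: separation case
        trials = [
            TrialRecord(LotteryPair(Lottery(50, 40, 0.9), Lottery(5, 0, 0.1)), "left", 1.0)
        ] * 40
        fit = fit_model(trials, "EU", n_starts=3, seed=2, min_trials=20)
        assert np.isfinite(fit.log_likelihood)
        assert isinstance(fit.converged, bool)

    def test_aicc_consistent_with_fields(self, battery):
        trials = simulate_choices(AgentSpec("EU", EUParams(0.85)), battery, seed=3)
        fit = fit_model(trials, "EU", n_starts=2, seed=4)
        assert fit.aicc == pytest.approx(aicc(fit.log_likelihood, fit.k, fit.n))
        assert fit.k == 1 and fit.n == 180
        assert fit.log_likelihood <= 0


class TestPrediction:
    def test_matches_argmax_oracle(self, random_trials):
        params = PTParams(0.9, 0.8, 0.7)
        sides, acc, ties = predict_choices(random_trials, params)
        arrays = trials_to_arrays(random_trials)
        correct = 0
        for i, t in enumerate(random_trials):
            ul = float(lottery_utility(t.pair.left.x1, t.pair.left.x2, t.pair.left.p, params)[0])
            ur = float(
                lottery_utility(t.pair.right.x1, t.pair.right.x2, t.pair.right.p, params)[0]
            )
            expected = "left" if ul > ur else "right"
            if ul != ur:
                assert sides[i] == expected
            if sides[i] == t.choice:
                correct += 1
        assert acc == pytest.approx(correct / len(random_trials))

    def test_self_consistency_with_sharp_preferences(self, battery):
        # near-deterministic agent: predictions should match simulated choices
        agent = AgentSpec("MVS", MVSParams(5.0, 0.0, 0.0))
        trials = simulate_choices(agent, battery, seed=12)
        _, acc, _ = predict_choices(trials, agent.params)
        assert acc > 0.95


class TestBehavioralBms:
    def test_identical_aicc_gives_uniform_frequencies(self):
        table = np.full((20, 3), 200.0)
        res = behavioral_bms(table, n_samples=50_000, seed=1)
        assert res.expected_freq == pytest.approx([1 / 3] * 3, abs=1e-6)

    def test_row_constant_invariance(self):
        rng = np.random.default_rng(4)
        table = rng.uniform(190, 210, size=(15, 3))
        shifted = table.copy()
        shifted[3] += 57.0
        r1 = behavioral_bms(table, n_samples=10_000, seed=2)
        r2 = behavioral_bms(shifted, n_samples=10_000, seed=2)
        assert r1.alpha == pytest.approx(r2.alpha, abs=1e-10)

    def test_strong_unanimous_preference(self):
        table = np.tile([220.0, 200.0, 220.0], (27, 1))  # PT better by 20 everywhere
        res = behavioral_bms(table, n_samples=100_000, seed=3)
        assert res.exceedance[1] > 0.95
        assert np.argmax(res.expected_freq) == 1

    def test_missing_cells_rejected(self):
        table = np.full((5, 3), 200.0)
        table[0, 0] = np.nan
        with pytest.raises(EstimationError):
            behavioral_bms(table)
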