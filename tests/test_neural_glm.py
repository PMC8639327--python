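import numpy as np
import pandas as pd
import pytest

from riskval import EUParams, PTParams
from riskval.neural_glm import (
    DesignError,
    DesignMatrix,
    ROITimeSeries,
    build_design_matrix,
    canonical_hrf,
    evidence_for_models,
    fit_glm,
    group_conjunction,
    log_evidence,
    roi_bms,
)
from riskval.synthetic import (
    AgentSpec,
    BoldSpec,
    attach_values,
    make_event_schedule,
    simulate_choices,
    simulate_roi_bold,
)

TR = 2.5


@pytest.fixture(scope="module")
def session(battery):
    """Trials, event schedule, and per-model value-attached events."""
    agent = AgentSpec("PT", PTParams(0.9, 0.8, 0.7))
    trials = simulate_choices(agent, battery, seed=21)
    schedule, n_scans = make_event_schedule(trials, seed=22)
    events = {
        "PT": attach_values(schedule, trials, agent.params),
        "EU": attach_values(schedule, trials, EUParams(0.85)),
    }
    return trials, schedule, events, n_scans


class TestHrf:
    def test_shape_constraints(self):
        h = canonical_hrf(TR, oversampling=16)
        dt = TR / 16
        t = np.arange(h.size) * dt
        assert h[0] == pytest.approx(0.0, abs=1e-6)
        peak_t = t[np.argmax(h)]
        assert 4.5 <= peak_t <= 6.5
        assert h.max() == pytest.approx(1.0)  # peak-normalized
        undershoot = h[(t > 10) & (t < 25)]
        assert undershoot.min() < 0
        assert np.isfinite(h.sum())

    def test_single_positive_peak(self):
        h = canonical_hrf(TR, oversampling=16)
        above = h > 0.5
        # one contiguous region above half maximum
        assert np.sum(np.diff(above.astype(int)) == 1) == 1

    def test_impulse_convolution_identity(self):
        h = canonical_hrf(1.0, oversampling=1)
        impulse = np.zeros(64)
        impulse[0] = 1.0
        out = np.convolve(impulse, h)[:64]
        assert out[: h.size] == pytest.approx(h)

    def test_derivatives_returned(self):
        h, td, dd = canonical_hrf(TR, include_derivatives=True)
        assert h.shape == td.shape == dd.shape


class TestDesignMatrix:
    def test_column_structure(self, session):
        _, schedule, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        # no missed trials in this session: 5 task columns + constant per run
        runs = sorted(set(schedule["run"]))
        per_run = ["valid", "state_value", "decision", "value_diff", "null"]
        expected = [f"r{r}_{c}" for r in runs for c in per_run] + [
            f"r{r}_constant" for r in runs
        ]
        assert sorted(dm.names) == sorted(expected)
        assert dm.X.shape == (n_scans * len(runs), len(expected))

    def test_missed_and_null_columns_omitted_when_absent(self, session):
        trials, _, _, _ = session
        ev = pd.DataFrame(
            {
                "onset": [10.0, 12.0],
                "duration": [2.0, 0.0],
                "trial_type": ["valid_trial", "decision"],
                "state_value": [30.0, np.nan],
                "value_difference": [np.nan, 5.0],
            }
        )
        dm = build_design_matrix(ev, 40, TR)
        assert not any("null" in n or "missed" in n for n in dm.names)

    def test_identical_values_give_identical_modulators(self, session):
        _, schedule, events, n_scans = session
        dm1 = build_design_matrix(events["PT"], n_scans, TR)
        dm2 = build_design_matrix(events["PT"].copy(), n_scans, TR)
        assert np.array_equal(dm1.X, dm2.X)

    def test_eu_pt_state_value_columns_highly_correlated(self, session):
        _, _, events, n_scans = session
        dm_eu = build_design_matrix(events["EU"], n_scans, TR)
        dm_pt = build_design_matrix(events["PT"], n_scans, TR)
        a = dm_eu.columns_matching("state_value").ravel()
        b = dm_pt.columns_matching("state_value").ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.8

    def test_events_beyond_range_rejected(self):
        ev = pd.DataFrame(
            {
                "onset": [200.0],
                "duration": [3.0],
                "trial_type": ["valid_trial"],
                "state_value": [10.0],
                "value_difference": [np.nan],
            }
        )
        with pytest.raises(DesignError):
            build_design_matrix(ev, 40, TR)

    def test_modulators_mean_centered(self, session):
        _, _, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        # mean-centered amplitudes make the modulator near-orthogonal to
        # the onset column, so its own mean is small relative to its scale
        for name in dm.names:
            if "state_value" in name:
                col = dm.column(name)
                assert abs(col.mean()) < 0.05 * col.std()


class TestGlmFit:
    def test_noiseless_recovery(self, session):
        _, _, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        rng = np.random.default_rng(0)
        beta_true = rng.normal(size=dm.X.shape[1])
        y = dm.X @ beta_true
        res = fit_glm(ROITimeSeries(y, TR, dm.runs), dm)
        assert res.betas == pytest.approx(beta_true, abs=1e-6)

    def test_null_t_distribution(self, session):
        _, _, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        rng = np.random.default_rng(1)
        tvals = []
        for _ in range(100):
            y = 100 + rng.normal(size=dm.X.shape[0])
            res = fit_glm(ROITimeSeries(y, TR, dm.runs), dm)
            tvals.append(res.t_stat("r0_state_value"))
        tvals = np.asarray(tvals)
        # central t: mean ~ 0, |t| > 3.1 should be very rare
        assert abs(tvals.mean()) < 0.4
        assert np.mean(np.abs(tvals) > 3.1) <= 0.02

    def test_zero_column_raises_rank_error(self, session):
        _, _, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        X = np.column_stack([dm.X, np.zeros(dm.X.shape[0])])
        bad = DesignMatrix(X, dm.names + ["dead"], dm.runs)
        with pytest.raises(DesignError, match="dead"):
            fit_glm(ROITimeSeries(X[:, 0] * 0 + 1.0, TR, dm.runs), bad)

    def test_prewhitening_reduces_residual_autocorrelation(self, session):
        _, _, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        spec = BoldSpec("PT", effect_state=0.5, effect_diff=0.5, ar1=0.4)
        ts = simulate_roi_bold(events["PT"], spec, n_scans, seed=5)
        res = fit_glm(ts, dm, prewhiten=True)
        r = res.residuals
        lag1 = np.corrcoef(r[1:], r[:-1])[0, 1]
        assert res.ar1_coef == pytest.approx(0.4, abs=0.12)
        assert abs(lag1) < 0.1


def brute_force_log_evidence(y, x, g):
    """2-D numerical integration of the marginal likelihood for a single
    g-prior regressor and Jeffreys noise prior.

    Integrates over (beta, log sigma^2) with the integrand shifted by its
    peak so the quadrature works on O(1) values.
    """
    from scipy.integrate import dblquad

    n = y.size
    xtx = float(x @ x)
    b_hat = float(x @ y) / xtx
    s2_hat = float((y - b_hat * x) @ (y - b_hat * x)) / n

    def logp(b, ls):
        sig2 = np.exp(ls)
        resid = y - b * x
        return (
            -0.5 * n * np.log(2 * np.pi * sig2)
            - 0.5 * resid @ resid / sig2
            - 0.5 * np.log(2 * np.pi * g * sig2 / xtx)
            - 0.5 * b**2 * xtx / (g * sig2)
        )  # the Jeffreys 1/sigma^2 cancels against the d(log sigma^2) jacobian

    shift = logp(b_hat, np.log(s2_hat))
    b_sd = np.sqrt(g * s2_hat / xtx)
    val, err = dblquad(
        lambda b, ls: np.exp(logp(b, ls) - shift),
        np.log(s2_hat) - 10,
        np.log(s2_hat) + 10,
        lambda ls: b_hat - 30 * b_sd,
        lambda ls: b_hat + 30 * b_sd,
        epsabs=1e-10,
        epsrel=1e-10,
    )
    assert err < 1e-6 * val
    return shift + np.log(val)


class TestLogEvidence:
    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(2)
        n = 20
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        g = float(n)
        closed = log_evidence(y, None, {"m": x}, g=g)["m"]
        numeric = brute_force_log_evidence(y, x, g)
        assert closed == pytest.approx(numeric, abs=1e-4)

    def test_identical_modulators_identical_evidence(self, session):
        _, _, events, n_scans = session
        dm = build_design_matrix(events["PT"], n_scans, TR)
        y = 100 + np.random.default_rng(3).normal(size=dm.X.shape[0])
        mods = dm.columns_matching("state_value")
        out = log_evidence(y, dm.columns_matching("constant"), {"a": mods, "b": mods.copy()})
        assert out["a"] == pytest.approx(out["b"], abs=1e-10)

    def test_scale_invariance_of_modulator(self):
        rng = np.random.default_rng(4)
        n = 50
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        e1 = log_evidence(y, None, {"m": x})["m"]
        e2 = log_evidence(y, None, {"m": 7.3 * x})["m"]
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_common_column_mismatch_rejected(self, session):
        _, _, events, n_scans = session
        dm_eu = build_design_matrix(events["EU"], n_scans, TR)
        dm_pt = build_design_matrix(events["PT"], n_scans, TR)
        y = ROITimeSeries(np.ones(dm_eu.X.shape[0]), TR, dm_eu.runs)
        # corrupt one common column of the second design
        bad = DesignMatrix(dm_pt.X.copy(), dm_pt.names, dm_pt.runs)
        bad.X[:, bad.names.index("r0_valid")] += 1.0
        with pytest.raises(DesignError):
            evidence_for_models(y, {"EU": dm_eu, "PT": bad}, prewhiten=False)

    def test_true_model_wins_at_high_snr(self, session):
        _, _, events, n_scans = session
        spec = BoldSpec("PT", effect_state=1.5, effect_diff=1.5, noise_sd=0.5)
        ts = simulate_roi_bold(events["PT"], spec, n_scans, seed=6)
        designs = {m: build_design_matrix(events[m], n_scans, TR) for m in ("EU", "PT")}
        le = evidence_for_models(ts, designs)
        assert le["PT"] > le["EU"]


class TestConjunction:
    @staticmethod
    def _maps(rng, shape, n, block=None, effect=0.0):
        maps = rng.normal(size=(n,) + shape)
        if block is not None:
            maps[(slice(None),) + block] += effect
        return maps

    def test_planted_block_recovered_and_extent_filters(self):
        rng = np.random.default_rng(7)
        shape, block = (10, 10, 10), (slice(2, 7), slice(2, 7), slice(2, 7))
        maps = {m: self._maps(rng, shape, 27, block, 1.5) for m in ("EU", "PT", "MVS")}
        mask = group_conjunction(maps, voxel_p=0.001, cluster_extent=20)
        blockmask = np.zeros(shape, bool)
        blockmask[block] = True
        assert mask[blockmask].mean() > 0.8
        assert (mask & ~blockmask).sum() < 5

    def test_two_model_signal_excluded(self):
        rng = np.random.default_rng(8)
        shape, block = (10, 10, 10), (slice(2, 7), slice(2, 7), slice(2, 7))
        maps = {
            "EU": self._maps(rng, shape, 27),
            "PT": self._maps(rng, shape, 27, block, 1.5),
            "MVS": self._maps(rng, shape, 27, block, 1.5),
        }
        with pytest.warns(UserWarning):
            mask = group_conjunction(maps, voxel_p=0.001, cluster_extent=20)
        assert mask.sum() == 0

    def test_monotone_in_voxel_p(self):
        rng = np.random.default_rng(9)
        shape, block = (8, 8, 8), (slice(1, 6), slice(1, 6), slice(1, 6))
        maps = {m: self._maps(rng, shape, 20, block, 1.0) for m in ("EU", "PT", "MVS")}
        mask_strict = group_conjunction(maps, voxel_p=0.0005, cluster_extent=10)
        mask_loose = group_conjunction(maps, voxel_p=0.01, cluster_extent=10)
        assert np.all(mask_loose[mask_strict])


class TestRoiBms:
    def test_single_voxel_equals_direct(self):
        rng = np.random.default_rng(10)
        ev = rng.normal(size=(12, 3))
        direct = roi_bms(ev, seed=1, n_samples=20_000)
        voxel = roi_bms(ev[:, :, None], seed=1, n_samples=20_000)
        assert direct.alpha == pytest.approx(voxel.alpha, abs=1e-12)

    def test_tied_evidence_uniform(self):
        ev = np.zeros((10, 3, 4))
        res = roi_bms(ev, seed=2, n_samples=100_000)
        assert res.exceedance == pytest.approx([1 / 3] * 3, abs=0.01)

    def test_empty_roi_rejected(self):
        with pytest.raises(DesignError):
            roi_bms(np.zeros((5, 3, 0)))
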