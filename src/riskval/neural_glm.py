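"""Event-related GLMs, linear-model evidence, conjunctions, and ROI BMS.

The scanner task is modeled with the regressor scheme: per run, a constant;
a boxcar from lottery onset to the response ("valid" trials) with a
state-value parametric modulator (the summed certainty equivalents of the
two options, mean-centered within run); a zero-duration decision event with
a value-difference modulator (|CE_L - CE_R|, mean-centered); null-trial
onsets; and 5-s missed-trial boxcars with their own state-value modulator.
All regressors are convolved with the canonical double-gamma HRF
(optionally with time and dispersion derivatives) on a fine microtime grid
and downsampled to scan times.

Model comparison uses a closed-form log marginal likelihood of the linear
model: nuisance (common) columns carry a flat prior and are handled by
projection, model-specific modulator columns carry a unit-information
Zellner g-prior (g = number of scans), and the noise variance a Jeffreys
prior. Because the data and the common columns are identical across the
three valuation models, the resulting log evidences are directly
comparable and feed the random-effects BMS machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from nilearn.glm.first_level import hemodynamic_models as _hm
from scipy import ndimage
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .bms import BMSResult, EvidenceMatrix, rfx_bms

EVENT_COLUMNS = ["onset", "duration", "trial_type", "state_value", "value_difference"]
TRIAL_TYPES = ("valid_trial", "decision", "null_trial", "missed_trial")
MISSED_DURATION = 5.0


class DesignError(ValueError):
    pass


@dataclass
class ROITimeSeries:
    """BOLD samples (arbitrary units) at fixed TR with run boundaries."""

    y: np.ndarray
    tr: float = 2.5
    runs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or not np.all(np.isfinite(self.y)):
            raise DesignError("BOLD series must be a finite 1-D array")
        if self.runs is None:
            self.runs = np.zeros(self.y.size, dtype=int)
        self.runs = np.asarray(self.runs, dtype=int)
        if self.runs.size != self.y.size:
            raise DesignError("run labels must match the number of scans")


@dataclass
class DesignMatrix:
    """Scans-by-regressors matrix with column names and run labels."""

    X: np.ndarray
    names: list[str]
    runs: np.ndarray

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def columns_matching(self, key: str) -> np.ndarray:
        idx = [i for i, n in enumerate(self.names) if key in n]
        return self.X[:, idx]


def validate_events(events: pd.DataFrame, n_scans: int, tr: float) -> pd.DataFrame:
    """Check the events table against the regressor-scheme invariants."""
    ev = events.copy()
    if "run" not in ev.columns:
        ev["run"] = 0
    missing = [c for c in ("onset", "duration", "trial_type") if c not in ev.columns]
    if missing:
        raise DesignError(f"events table lacks columns {missing}")
    bad = set(ev["trial_type"]) - set(TRIAL_TYPES)
    if bad:
        raise DesignError(f"unknown trial types {sorted(bad)}")
    if (ev["duration"] < 0).any():
        raise DesignError("durations must be nonnegative")
    for run, sub in ev.groupby("run"):
        if not sub["onset"].is_monotonic_increasing:
            raise DesignError(f"onsets must be nondecreasing within run {run}")
        if ((sub["onset"] + sub["duration"]) > n_scans * tr).any():
            raise DesignError(f"events extend beyond the scan range in run {run}")
        dec = sub[sub["trial_type"] == "decision"]
        if (dec["duration"] != 0).any():
            raise DesignError("decision events must have zero duration")
        mis = sub[sub["trial_type"] == "missed_trial"]
        if (mis["duration"] != MISSED_DURATION).any():
            raise DesignError(f"missed trials must last {MISSED_DURATION} s")
    return ev


def canonical_hrf(
    tr: float, *, oversampling: int = 16, include_derivatives: bool = False
) -> np.ndarray | tuple[np.ndarray, ...]:
    """Canonical double-gamma HRF sampled at ``tr / oversampling``.

    Peak at ~6 s, undershoot at ~16 s with 1:6 peak/undershoot ratio and
    32-s support; peak-normalized. With ``include_derivatives`` the
    temporal and dispersion derivative kernels are returned as well (scaled
    by the same constant so relative amplitudes are preserved).
    """
    if tr <= 0:
        raise DesignError("tr must be positive")
    hrf = _hm.spm_hrf(tr, oversampling=oversampling)
    scale = np.max(hrf)
    hrf = hrf / scale
    if not include_derivatives:
        return hrf
    td = _hm.spm_time_derivative(tr, oversampling=oversampling) / scale
    dd = _hm.spm_dispersion_derivative(tr, oversampling=oversampling) / scale
    return hrf, td, dd


def _stick_function(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_fine: int,
    dt: float,
) -> np.ndarray:
    """Neural signal on the microtime grid: boxcars, or unit sticks for
    zero-duration events."""
    x = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        x[i0 : min(i1, n_fine)] += amp
    return x


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr: float = 2.5,
    *,
    oversampling: int = 16,
    include_derivatives: bool = False,
) -> DesignMatrix:
    """HRF-convolved design matrix for the task's regressor scheme.

    ``n_scans`` is per run; runs are identified by an optional ``run``
    column (a single run otherwise) and stacked with one constant column
    per run. Parametric-modulator values are mean-centered within run
    before scaling their event sticks, decorrelating them from the onset
    regressors. Column groups whose events are absent are omitted.
    """
    ev = validate_events(events, n_scans, tr)
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    kernels = canonical_hrf(tr, oversampling=oversampling, include_derivatives=include_derivatives)
    if not include_derivatives:
        kernels = (kernels,)
    deriv_tags = ["", "_td", "_dd"][: len(kernels)]

    run_ids = sorted(ev["run"].unique())
    blocks: list[np.ndarray] = []
    names: list[str] = []
    col_index: dict[str, int] = {}

    def regressors_for_run(sub: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
        out = []
        valid = sub[sub["trial_type"] == "valid_trial"]
        if len(valid):
            ons, dur = valid["onset"].to_numpy(), valid["duration"].to_numpy()
            out.append(("valid", _stick_function(ons, dur, np.ones(len(valid)), n_fine, dt)))
            sv = valid["state_value"].to_numpy(dtype=float)
            out.append(("state_value", _stick_function(ons, dur, sv - sv.mean(), n_fine, dt)))
        dec = sub[sub["trial_type"] == "decision"]
        if len(dec):
            ons = dec["onset"].to_numpy()
            zeros = np.zeros(len(dec))
            out.append(("decision", _stick_function(ons, zeros, np.ones(len(dec)), n_fine, dt)))
            vd = dec["value_difference"].to_numpy(dtype=float)
            out.append(("value_diff", _stick_function(ons, zeros, vd - vd.mean(), n_fine, dt)))
        null = sub[sub["trial_type"] == "null_trial"]
        if len(null):
            ons = null["onset"].to_numpy()
            out.append(
                ("null", _stick_function(ons, np.zeros(len(null)), np.ones(len(null)), n_fine, dt))
            )
        mis = sub[sub["trial_type"] == "missed_trial"]
        if len(mis):
            ons, dur = mis["onset"].to_numpy(), mis["duration"].to_numpy()
            out.append(("missed", _stick_function(ons, dur, np.ones(len(mis)), n_fine, dt)))
            sv = mis["state_value"].to_numpy(dtype=float)
            out.append(
                ("missed_state_value", _stick_function(ons, dur, sv - sv.mean(), n_fine, dt))
            )
        return out

    per_run_cols: dict[int, dict[str, np.ndarray]] = {}
    for run in run_ids:
        sub = ev[ev["run"] == run]
        cols: dict[str, np.ndarray] = {}
        for name, neural in regressors_for_run(sub):
            for kern, tag in zip(kernels, deriv_tags):
                conv = np.convolve(neural, kern)[:n_fine]
                cols[name + tag] = conv[::oversampling]
        per_run_cols[run] = cols

    all_names = []
    for run in run_ids:
        for n in per_run_cols[run]:
            if n not in all_names:
                all_names.append(n)
    total = n_scans * len(run_ids)
    columns: list[np.ndarray] = []
    names = []
    for ri, run in enumerate(run_ids):
        for name in all_names:
            if name in per_run_cols[run]:
                col = np.zeros(total)
                col[ri * n_scans : (ri + 1) * n_scans] = per_run_cols[run][name]
                columns.append(col)
                names.append(f"r{run}_{name}")
    for ri, run in enumerate(run_ids):
        col = np.zeros(total)
        col[ri * n_scans : (ri + 1) * n_scans] = 1.0
        columns.append(col)
        names.append(f"r{run}_constant")
    runs = np.repeat(run_ids, n_scans)
    return DesignMatrix(np.column_stack(columns), names, runs)


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------


@dataclass
class GLMResult:
    betas: np.ndarray
    names: list[str]
    sigma2: float
    df: int
    xtx_inv: np.ndarray
    residuals: np.ndarray
    ar1_coef: float | None = None

    def contrast_t(self, contrast: Sequence[float]) -> float:
        c = np.asarray(contrast, dtype=float)
        se = np.sqrt(self.sigma2 * c @ self.xtx_inv @ c)
        return float(c @ self.betas / se)

    def t_stat(self, name: str) -> float:
        c = np.zeros(len(self.names))
        c[self.names.index(name)] = 1.0
        return self.contrast_t(c)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        norms = np.linalg.norm(X, axis=0)
        _, R = np.linalg.qr(X / np.where(norms > 0, norms, 1.0))
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 or norms[i] == 0]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ols(y: np.ndarray, X: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def fit_glm(
    y: ROITimeSeries | np.ndarray,
    design: DesignMatrix,
    *,
    prewhiten: bool = False,
) -> GLMResult:
    """Ordinary least squares with optional AR(1) prewhitening.

    The AR coefficient is estimated from the OLS residuals (lag-1
    autocorrelation within runs) and the model refitted on
    Cochrane–Orcutt-transformed data, restarting at each run boundary.
    """
    ts = y if isinstance(y, ROITimeSeries) else ROITimeSeries(np.asarray(y, float))
    if ts.y.size != design.X.shape[0]:
        raise DesignError("scan count does not match the design matrix")
    _check_rank(design.X, design.names)
    X = design.X
    yy = ts.y
    beta, resid = _ols(yy, X)
    rho = None
    if prewhiten:
        num = den = 0.0
        for run in np.unique(design.runs):
            r = resid[design.runs == run]
            num += float(r[1:] @ r[:-1])
            den += float(r @ r)
        rho = num / den if den > 0 else 0.0
        yw = yy.copy()
        Xw = X.copy()
        for run in np.unique(design.runs):
            idx = np.where(design.runs == run)[0]
            yw[idx[1:]] = yy[idx[1:]] - rho * yy[idx[:-1]]
            Xw[idx[1:]] = X[idx[1:]] - rho * X[idx[:-1]]
            yw[idx[0]] *= np.sqrt(1 - rho**2)
            Xw[idx[0]] *= np.sqrt(1 - rho**2)
        beta, resid = _ols(yw, Xw)
        X = Xw
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return GLMResult(beta, list(design.names), sigma2, df, xtx_inv, resid, rho)


# ---------------------------------------------------------------------------
# Closed-form model evidence
# ---------------------------------------------------------------------------


def log_evidence(
    y: np.ndarray,
    X_common: np.ndarray | None,
    modulators_per_model: Mapping[str, np.ndarray],
    *,
    g: float | None = None,
) -> dict[str, float]:
    """Log marginal likelihood of the linear model per valuation model.

    Common (nuisance) columns carry an improper flat prior and are removed
    by projecting data and modulators onto their orthogonal complement;
    the model-specific modulator columns carry a Zellner g-prior
    ``beta ~ N(0, g sigma^2 (X'X)^{-1})`` with ``g`` defaulting to the
    number of scans (unit information), and ``sigma^2`` a Jeffreys prior.
    The additive constant from the flat prior is common to all models, so
    differences between the returned values are proper log Bayes factors.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if g is None:
        g = float(n)
    if X_common is None or X_common.size == 0:
        Xc = np.empty((n, 0))
    else:
        Xc = np.atleast_2d(np.asarray(X_common, dtype=float))
        if Xc.shape[0] != n:
            Xc = Xc.T
    rank_c = np.linalg.matrix_rank(Xc) if Xc.shape[1] else 0
    if Xc.shape[1]:
        pinv = np.linalg.pinv(Xc)
        My = y - Xc @ (pinv @ y)
    else:
        pinv = None
        My = y
    n_star = n - rank_c
    yMy = float(My @ My)
    out: dict[str, float] = {}
    for name, Xm in modulators_per_model.items():
        Xm = np.asarray(Xm, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        if Xm.shape[0] != n:
            raise DesignError("modulator rows must equal the number of scans")
        MXm = Xm - Xc @ (pinv @ Xm) if Xc.shape[1] else Xm
        p_m = Xm.shape[1]
        if np.linalg.matrix_rank(MXm) < p_m:
            raise DesignError(
                f"modulators for {name!r} are collinear with the common columns"
            )
        coef, _, _, _ = np.linalg.lstsq(MXm, My, rcond=None)
        ss_model = float((MXm @ coef) @ (MXm @ coef))
        q = yMy - (g / (1.0 + g)) * ss_model
        out[name] = float(
            -(n_star / 2.0) * np.log(2.0 * np.pi)
            + gammaln(n_star / 2.0)
            - (p_m / 2.0) * np.log1p(g)
            - (n_star / 2.0) * np.log(q / 2.0)
        )
    return out


def _estimate_ar1(resid: np.ndarray, runs: np.ndarray) -> float:
    num = den = 0.0
    for run in np.unique(runs):
        r = resid[runs == run]
        num += float(r[1:] @ r[:-1])
        den += float(r @ r)
    return num / den if den > 0 else 0.0


def _whiten(arr: np.ndarray, runs: np.ndarray, rho: float) -> np.ndarray:
    out = arr.copy()
    for run in np.unique(runs):
        idx = np.where(runs == run)[0]
        out[idx[1:]] = arr[idx[1:]] - rho * arr[idx[:-1]]
        out[idx[0]] = arr[idx[0]] * np.sqrt(1 - rho**2)
    return out


def evidence_for_models(
    ts: ROITimeSeries,
    designs: Mapping[str, DesignMatrix],
    *,
    modulator_keys: tuple[str, ...] = ("state_value", "value_diff"),
    g: float | None = None,
    prewhiten: bool = True,
) -> dict[str, float]:
    """Per-model evidence from full design matrices sharing common columns.

    The model-specific partition holds the parametric-modulator columns
    (state value and value difference by default); everything else —
    onsets, nulls, missed trials, derivatives, constants — is common. The
    common partition is taken from the first design and must be identical
    across models.

    The closed-form evidence assumes white noise, so by default the series
    and all columns are AR(1)-prewhitened first. The AR coefficient is
    estimated from the residuals of an OLS fit on the *union* of all
    models' columns and the identical transform is applied everywhere —
    otherwise autocorrelated noise systematically favors whichever model's
    modulators happen to absorb more low-frequency variance, and the
    evidences would stop being comparable.
    """
    names = list(designs)
    first = designs[names[0]]

    def split(dm: DesignMatrix):
        mod_idx = [
            i
            for i, n in enumerate(dm.names)
            if any(n.endswith(k) for k in modulator_keys)
        ]
        com_idx = [i for i in range(len(dm.names)) if i not in mod_idx]
        return dm.X[:, com_idx], dm.X[:, mod_idx]

    X_common, _ = split(first)
    modulators = {}
    for name in names:
        Xc, Xm = split(designs[name])
        if Xc.shape != X_common.shape or not np.allclose(Xc, X_common):
            raise DesignError("common columns differ across models; evidences not comparable")
        modulators[name] = Xm
    y = ts.y
    if prewhiten:
        union = np.column_stack([X_common] + [modulators[n] for n in names])
        beta, _, _, _ = np.linalg.lstsq(union, y, rcond=None)
        rho = _estimate_ar1(y - union @ beta, ts.runs)
        y = _whiten(y, ts.runs, rho)
        X_common = _whiten(X_common, ts.runs, rho)
        modulators = {n: _whiten(m, ts.runs, rho) for n, m in modulators.items()}
    return log_evidence(y, X_common, modulators, g=g)


# ---------------------------------------------------------------------------
# Conjunction masks and ROI-level BMS
# ---------------------------------------------------------------------------


def _cluster_filter(mask: np.ndarray, extent: int) -> np.ndarray:
    structure = ndimage.generate_binary_structure(mask.ndim, 1)  # 6-connected in 3-D
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= extent
    return keep[labels]


def group_conjunction(
    contrast_maps: Mapping[str, np.ndarray],
    voxel_p: float = 0.001,
    cluster_extent: int = 165,
) -> np.ndarray:
    """Voxelwise AND of per-model thresholded group activation maps.

    For each model, a one-sample t-test across subjects is thresholded at
    the (one-sided, uncorrected) voxel p-value, 6-connected clusters below
    the extent are discarded, and the surviving maps are intersected. An
    empty intersection is returned with a warning.
    """
    masks = []
    for name, maps in contrast_maps.items():
        maps = np.asarray(maps, dtype=float)
        n = maps.shape[0]
        mean = maps.mean(axis=0)
        sd = maps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
        p = t_dist.sf(t, df=n - 1)
        masks.append(_cluster_filter(p < voxel_p, cluster_extent))
    out = np.logical_and.reduce(masks)
    if not out.any():
        warnings.warn("conjunction mask is empty")
    return out


def roi_bms(
    evidence: np.ndarray,
    models: Sequence[str] = ("EU", "PT", "MVS"),
    *,
    n_samples: int = 1_000_000,
    seed: int | None = 0,
) -> BMSResult:
    """Random-effects BMS on ROI-averaged log evidences.

    ``evidence`` is subjects x models, or subjects x models x voxels, in
    which case the voxelwise log evidences are first averaged within the
    ROI per subject and model.
    """
    ev = np.asarray(evidence, dtype=float)
    if ev.ndim == 3:
        if ev.shape[2] == 0:
            raise DesignError("ROI contains zero voxels")
        ev = ev.mean(axis=2)
    if ev.ndim != 2:
        raise DesignError("evidence must be 2-D or 3-D")
    return rfx_bms(EvidenceMatrix(ev, models=list(models)), n_samples=n_samples, seed=seed)
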