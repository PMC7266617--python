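"""First-level GLM: HRF construction, design matrices, OLS, delay search, PSC.

The hemodynamic response function is a difference of two gamma densities
whose shape parameters are solved numerically so that the response peaks at
``time_to_peak_s`` and the undershoot minimum falls at
``time_to_undershoot_s``, with an undershoot-to-peak amplitude ratio of
1:6. Task regressors are boxcars (trial onset to trial offset) convolved
with this kernel and scaled so that an isolated trial's regressor peaks at
1, which makes percent signal change well defined as 100 * beta /
run-intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class HRFSpec:
    """Two-gamma HRF landmarks and sampling parameters.

    ``onset_delay_s`` shifts the whole kernel later in time; the study's
    grid search considers delays of 0, 0.5 and 1 s.
    """

    time_to_peak_s: float = 5.5
    time_to_undershoot_s: float = 12.5
    onset_delay_s: float = 0.0
    duration_s: float = 32.0
    dt_s: float = 0.1
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not 0 < self.time_to_peak_s < self.time_to_undershoot_s:
            raise ValueError("need 0 < time_to_peak < time_to_undershoot")
        if self.onset_delay_s < 0:
            raise ValueError("onset_delay_s must be non-negative")


def _two_gamma(t, p1, p2, c, b=1.0):
    """h(t) = gampdf(t; p1, b) - c * gampdf(t; p2, b)."""
    t = np.asarray(t, dtype=float)
    return stats.gamma.pdf(t, p1, scale=b) - c * stats.gamma.pdf(t, p2, scale=b)


def _dh(t, p1, p2, c, b):
    # d/dt gampdf(t; p, b) = gampdf(t; p, b) * ((p - 1)/t - 1/b)
    g1 = stats.gamma.pdf(t, p1, scale=b) * ((p1 - 1.0) / t - 1.0 / b)
    g2 = stats.gamma.pdf(t, p2, scale=b) * ((p2 - 1.0) / t - 1.0 / b)
    return g1 - c * g2


def _landmarks(p1, p2, c, b, t_hi):
    """Continuous-time (t_max, h_max, t_min, h_min) of the kernel.

    Grid scan for the extrema, then 1-D root refinement of h' in a bracket
    around each.
    """
    grid = np.arange(0.05, t_hi, 0.05)
    h = _two_gamma(grid, p1, p2, c, b)
    i_max, i_min = int(np.argmax(h)), int(np.argmin(h))
    if not (0 < i_max < i_min < len(grid) - 1) or h[i_min] >= 0:
        return None

    def refine(i):
        lo, hi = grid[i - 1], grid[i + 1]
        if _dh(lo, p1, p2, c, b) * _dh(hi, p1, p2, c, b) > 0:
            return grid[i]
        return optimize.brentq(_dh, lo, hi, args=(p1, p2, c, b), xtol=1e-10)

    t_max, t_min = refine(i_max), refine(i_min)
    return (t_max, float(_two_gamma(t_max, p1, p2, c, b)),
            t_min, float(_two_gamma(t_min, p1, p2, c, b)))


@lru_cache(maxsize=32)
def _solve_two_gamma(peak: float, undershoot: float, ratio: float):
    """Solve (p1, p2, c, b) so the continuous kernel has its maximum at
    ``peak``, its minimum at ``undershoot`` and |min|/max = ``ratio``.

    Gamma shapes are parameterized as p1 = 1 + exp(x0), p2 = p1 + exp(x1)
    so the positive lobe always precedes the undershoot lobe; the shared
    scale b gives the family enough freedom for any valid landmark pair.
    """
    t_hi = 3.0 * undershoot

    def residuals(x):
        p1 = 1.0 + math.exp(x[0])
        p2 = p1 + math.exp(x[1])
        c = math.exp(x[2])
        b = math.exp(x[3])
        lm = _landmarks(p1, p2, c, b, t_hi)
        if lm is None:
            return np.array([10.0, 10.0, 10.0])
        t_max, h_max, t_min, h_min = lm
        return np.array([(t_max - peak) / peak,
                         (t_min - undershoot) / undershoot,
                         (-h_min) / h_max - ratio])

    last_err = None
    for b0 in (1.0, 0.5, 2.0):
        x0 = np.array([math.log(peak / b0), math.log(undershoot - peak),
                       math.log(ratio), math.log(b0)])
        sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14,
                                     gtol=1e-14, diff_step=1e-6)
        if np.max(np.abs(sol.fun)) <= 1e-6:
            p1 = 1.0 + math.exp(sol.x[0])
            p2 = p1 + math.exp(sol.x[1])
            return p1, p2, math.exp(sol.x[2]), math.exp(sol.x[3])
        last_err = np.max(np.abs(sol.fun))
    raise ValueError(
        f"no two-gamma kernel with peak {peak} s / undershoot "
        f"{undershoot} s / ratio {ratio} (residual {last_err:.2g})")


def hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sample the HRF kernel on ``arange(0, duration_s + dt, dt)``.

    The kernel starts at 0, peaks at 1 at ``time_to_peak_s`` and has its
    undershoot minimum at ``time_to_undershoot_s`` (each within half a
    sample of the requested landmark). ``onset_delay_s`` right-shifts the
    kernel, padding with zeros.
    """
    p1, p2, c, b = _solve_two_gamma(
        spec.time_to_peak_s, spec.time_to_undershoot_s, spec.undershoot_ratio
    )
    t = np.arange(0.0, spec.duration_s + spec.dt_s / 2, spec.dt_s)
    shifted = t - spec.onset_delay_s
    vals = np.where(shifted > 0,
                    _two_gamma(np.maximum(shifted, 1e-12), p1, p2, c, b), 0.0)
    peak_val = _two_gamma(spec.time_to_peak_s, p1, p2, c, b)
    return vals / peak_val


def _convolve_boxcars(onsets, durations, kernel, n_timepoints, tr_s, dt_s):
    """Continuous-time boxcar (x) kernel, sampled at the TR grid.

    Returns the regressor sampled at t = 0, TR, 2 TR, ... The fine-grid
    convolution is scaled by dt so its height approximates the continuous
    convolution integral; the caller renormalizes to unit single-trial
    peak, so only relative shape matters.
    """
    n_fine = int(np.ceil(n_timepoints * tr_s / dt_s)) + len(kernel) + 1
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt_s))
        i1 = int(round((onset + dur) / dt_s))
        box[i0:i1] += 1.0  # overlapping trials of one condition sum
    conv = np.convolve(box, kernel)[:n_fine] * dt_s
    idx = np.round(np.arange(n_timepoints) * tr_s / dt_s).astype(int)
    return conv[idx]


def _single_trial_peak(duration, kernel, dt_s):
    box_len = max(int(round(duration / dt_s)), 1)
    conv = np.convolve(np.ones(box_len), kernel) * dt_s
    return conv.max()


def build_design(
    events: pd.DataFrame,
    kernel: np.ndarray,
    n_timepoints: int,
    tr_s: float = 1.0,
    dt_s: float = 0.1,
    conditions=None,
):
    """Build a single-run GLM design matrix from an events table.

    ``events`` uses BIDS-style columns ``onset``, ``duration``,
    ``trial_type``. One column per condition (boxcar convolved with
    ``kernel``, scaled so an isolated trial of that condition's duration
    peaks at 1) plus a trailing intercept column.

    Returns ``(X, condition_order)`` where ``X`` is ``(n_timepoints,
    n_conditions + 1)``.
    """
    if conditions is None:
        conditions = sorted(events["trial_type"].unique().tolist())
    cols = []
    for cond in conditions:
        sub = events[events["trial_type"] == cond]
        if len(sub) == 0:
            raise ValueError(f"condition {cond!r} has no events (zero column)")
        if (sub["onset"] < 0).any() or (
            (sub["onset"] + sub["duration"]) > n_timepoints * tr_s
        ).any():
            raise ValueError(f"events of condition {cond!r} fall outside the run")
        col = _convolve_boxcars(
            sub["onset"].to_numpy(), sub["duration"].to_numpy(),
            kernel, n_timepoints, tr_s, dt_s,
        )
        scale = _single_trial_peak(float(sub["duration"].iloc[0]), kernel, dt_s)
        cols.append(col / scale)
    X = np.column_stack(cols + [np.ones(n_timepoints)])
    return X, list(conditions)


@dataclass
class FirstLevelGLMResults:
    """Per-run OLS estimates of condition activations.

    Attributes
    ----------
    betas : (n_conditions * n_runs, n_voxels)
        Activation estimate for every condition in every run.
    condition_ids, run_ids : per-row labels for ``betas``.
    intercepts : (n_runs, n_voxels) run baselines.
    residuals : (n_timepoints_total, n_voxels) stacked OLS residuals.
    dof : total residual degrees of freedom.
    delay_chosen_s : HRF onset delay used (from the grid search, if any).
    """

    betas: np.ndarray
    condition_ids: np.ndarray
    run_ids: np.ndarray
    intercepts: np.ndarray
    runs: list
    residuals: np.ndarray
    dof: int
    delay_chosen_s: float = 0.0

    def percent_signal_change(self, condition_set=None) -> np.ndarray:
        return percent_signal_change(self, condition_set)

    def to_pattern_dataset(self, sequence_type=None, session=None):
        from .datasets import PatternDataset

        return PatternDataset(
            data=self.betas,
            condition_ids=self.condition_ids,
            partition_ids=self.run_ids,
            sequence_type=sequence_type,
            session=session,
            residuals=self.residuals,
            dof=self.dof,
        )

    def summary(self) -> str:
        n_cond = len(set(self.condition_ids.tolist()))
        lines = [
            "First-level GLM results",
            "=" * 47,
            f"runs:                {len(self.runs)}",
            f"conditions:          {n_cond}",
            f"voxels:              {self.betas.shape[1]}",
            f"residual dof:        {self.dof}",
            f"HRF onset delay:     {self.delay_chosen_s:.1f} s",
            f"mean |beta|:         {np.abs(self.betas).mean():.4f}",
            f"mean intercept:      {self.intercepts.mean():.4f}",
        ]
        return "\n".join(lines)


class FirstLevelGLM:
    """Ordinary-least-squares first-level model, fitted run by run.

    Parameters
    ----------
    timeseries
        Mapping ``run -> (n_timepoints, n_voxels)`` BOLD array (or a list,
        in which case runs are numbered from 0).
    events
        Events table with columns ``run``, ``onset``, ``duration``,
        ``trial_type`` and optionally ``is_error``.
    tr_s
        Sampling interval of the time series in seconds.
    hrf_spec
        HRF landmarks; ``onset_delay_s`` is overridden by
        :func:`select_delay` when a grid search is requested.
    exclude_errors
        If true, error trials (``is_error`` truthy) are removed from their
        condition regressor and modelled by one nuisance regressor per run.
    """

    def __init__(self, timeseries, events: pd.DataFrame, tr_s: float = 1.0,
                 hrf_spec: HRFSpec = HRFSpec(), exclude_errors: bool = False):
        if isinstance(timeseries, (list, tuple)):
            timeseries = {i: y for i, y in enumerate(timeseries)}
        self.timeseries = {r: np.asarray(y, dtype=float)
                           for r, y in timeseries.items()}
        self.events = events.reset_index(drop=True)
        self.tr_s = float(tr_s)
        self.hrf_spec = hrf_spec
        self.exclude_errors = bool(exclude_errors)
        missing = set(self.events["run"].unique()) - set(self.timeseries)
        if missing:
            raise ValueError(f"events reference unknown runs {sorted(missing)}")

    def _run_design(self, run, kernel, conditions):
        ev = self.events[self.events["run"] == run]
        n_t = self.timeseries[run].shape[0]
        nuisance = None
        if self.exclude_errors and "is_error" in ev.columns and ev["is_error"].any():
            err = ev[ev["is_error"].astype(bool)]
            ev = ev[~ev["is_error"].astype(bool)]
            nuisance = _convolve_boxcars(
                err["onset"].to_numpy(), err["duration"].to_numpy(),
                kernel, n_t, self.tr_s, self.hrf_spec.dt_s,
            )
            nuisance = nuisance / _single_trial_peak(
                float(err["duration"].iloc[0]), kernel, self.hrf_spec.dt_s)
        X, conds = build_design(ev, kernel, n_t, self.tr_s,
                                self.hrf_spec.dt_s, conditions)
        if nuisance is not None:
            # nuisance column inserted before the intercept
            X = np.column_stack([X[:, :-1], nuisance, X[:, -1]])
        return X, conds, (nuisance is not None)

    def fit(self, delay_s: float | None = None) -> FirstLevelGLMResults:
        spec = self.hrf_spec if delay_s is None else replace(
            self.hrf_spec, onset_delay_s=delay_s)
        kernel = hrf(spec)
        conditions = sorted(self.events["trial_type"].unique().tolist())
        runs = sorted(self.timeseries.keys())
        betas, cond_ids, run_ids, intercepts, resids = [], [], [], [], []
        dof = 0
        for run in runs:
            y = self.timeseries[run]
            X, conds, has_nuis = self._run_design(run, kernel, conditions)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"rank-deficient design in run {run!r}")
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            betas.append(coef[: len(conds)])
            cond_ids.extend(conds)
            run_ids.extend([run] * len(conds))
            intercepts.append(coef[-1])
            resids.append(y - X @ coef)
            dof += y.shape[0] - X.shape[1]
        res = FirstLevelGLMResults(
            betas=np.vstack(betas),
            condition_ids=np.array(cond_ids),
            run_ids=np.array(run_ids),
            intercepts=np.vstack(intercepts),
            runs=runs,
            residuals=np.vstack(resids),
            dof=dof,
            delay_chosen_s=spec.onset_delay_s,
        )
        if not np.all(np.isfinite(res.betas)):
            raise ValueError("non-finite betas")
        return res


def fit_glm(timeseries, events, spec: HRFSpec = HRFSpec(), tr_s: float = 1.0,
            exclude_errors: bool = False) -> FirstLevelGLMResults:
    """Functional wrapper around :class:`FirstLevelGLM`."""
    return FirstLevelGLM(timeseries, events, tr_s=tr_s, hrf_spec=spec,
                         exclude_errors=exclude_errors).fit()


def select_delay(timeseries, events, roi_voxels=None, tr_s: float = 1.0,
                 delays=(0.0, 0.5, 1.0), hrf_spec: HRFSpec = HRFSpec()) -> float:
    """Grid search over HRF onset delays on the mean ROI time course.

    Fits the GLM to the voxel-mean response of ``roi_voxels`` for every
    candidate delay and returns the delay with the highest R^2 (variance of
    the fitted values relative to the data, pooled over runs). Ties break
    toward the smaller delay. Per the study protocol this is run on
    session-1 data and the chosen delay is reused for all later sessions.
    """
    if isinstance(timeseries, (list, tuple)):
        timeseries = {i: y for i, y in enumerate(timeseries)}
    roi = {r: np.asarray(y, dtype=float) for r, y in timeseries.items()}
    if roi_voxels is not None:
        roi_voxels = np.asarray(roi_voxels, dtype=int)
        if roi_voxels.size == 0:
            raise ValueError("ROI must contain at least one voxel")
        roi = {r: y[:, roi_voxels] for r, y in roi.items()}
    mean_ts = {r: y.mean(axis=1, keepdims=True) for r, y in roi.items()}
    best_delay, best_r2 = None, -np.inf
    for delay in sorted(delays):
        model = FirstLevelGLM(mean_ts, events, tr_s=tr_s,
                              hrf_spec=replace(hrf_spec, onset_delay_s=delay))
        ss_res, ss_tot = 0.0, 0.0
        res = model.fit()
        for r in model.timeseries:
            y = mean_ts[r][:, 0]
            ss_tot += ((y - y.mean()) ** 2).sum()
        ss_res = (res.residuals[:, 0] ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if r2 > best_r2 + 1e-12:
            best_delay, best_r2 = delay, r2
    return best_delay


def percent_signal_change(glm: FirstLevelGLMResults, condition_set=None) -> np.ndarray:
    """Percent signal change of a condition set relative to baseline.

    PSC = 100 * mean(beta over the set and runs) / mean(intercept over
    runs), per voxel. Valid because an isolated-trial regressor peaks at 1.
    Voxels with (near-)zero intercept come back NaN for downstream masking.
    """
    if condition_set is None:
        mask = np.ones(len(glm.condition_ids), dtype=bool)
    else:
        wanted = set(condition_set)
        mask = np.array([c in wanted for c in glm.condition_ids])
        if not mask.any():
            raise ValueError("condition_set matches no estimated condition")
    mean_beta = glm.betas[mask].mean(axis=0)
    mean_intercept = glm.intercepts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * mean_beta / mean_intercept
    psc[np.abs(mean_intercept) < 1e-12] = np.nan
    return psc
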