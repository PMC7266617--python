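"""Synthetic study generator.

Emulates the statistical structure of a longitudinal motor-sequence
learning experiment: 26 subjects scanned in 4 sessions of 8 runs, each run
presenting 6 trained and 6 untrained 9-digit sequences, every sequence
executed twice in a row for a total of six repetitions per run. Each trial
is 1 s preparation + 3.5 s execution/feedback + 0.5 s inter-trial interval
(5 s total); five 10-s rest periods are inserted at random trial
boundaries. True sequence-specific activity patterns are drawn from a
zero-mean Gaussian whose cross-session correlation structure is
configurable per sequence type, so pattern-stability analyses have a known
ground truth. Movement times follow an exponential learning curve from 3.2
s to 1.2 s for trained sequences, with a shallower transfer curve for
untrained ones.

Everything is a pure function of ``(config, seed)``: equal seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import PatternDataset, TRAINED, UNTRAINED

#: default per-type cross-session correlations of true sequence patterns.
#: Trained patterns reorganize early (low week1-week2 correlation) and
#: stabilize later; untrained patterns stay comparatively stable.
DEFAULT_R_TRUE = {
    TRAINED: np.array([
        [1.00, 0.37, 0.30, 0.25],
        [0.37, 1.00, 0.60, 0.50],
        [0.30, 0.60, 1.00, 0.80],
        [0.25, 0.50, 0.80, 1.00],
    ]),
    UNTRAINED: np.array([
        [1.00, 0.65, 0.60, 0.55],
        [0.65, 1.00, 0.65, 0.60],
        [0.60, 0.65, 1.00, 0.80],
        [0.55, 0.60, 0.80, 1.00],
    ]),
}

#: default per-session error rates (rows = sessions, cols = trained,
#: untrained), matching the reported scanner error rates.
DEFAULT_ERROR_RATE = np.array([
    [0.14, 0.15],
    [0.08, 0.14],
    [0.06, 0.09],
    [0.14, 0.13],
])


@dataclass
class SimConfig:
    """Study-design and generative parameters of the synthetic experiment.

    Parameters
    ----------
    signal_var
        Per-session variance of true sequence patterns (signal units^2);
        scalar, per-session array, or ``{sequence_type: array}``.
    noise_var
        Variance of run-level estimation noise around the true pattern.
    r_true
        Cross-session correlation of true patterns: scalar (all session
        pairs, both types) or ``{sequence_type: (n_sessions x n_sessions)
        correlation matrix}``. Validated positive semi-definite.
    voxel_cov
        ``"identity"`` or ``("ar1", rho)`` spatial noise covariance.
    error_rate
        Scalar or ``(n_sessions, 2)`` array (columns trained, untrained).
    n_residual_rows
        Residual rows emitted per run for noise-covariance estimation.
    """

    n_subjects: int = 26
    n_sessions: int = 4
    n_runs: int = 8
    n_sequences_per_type: int = 6
    n_voxels: int = 160
    signal_var: object = 1.0
    noise_var: float = 8.0
    r_true: object = None
    voxel_cov: object = "identity"
    mt_start_s: float = 3.2
    mt_end_s: float = 1.2
    mt_noise_sigma: float = 0.1
    mt_tau_trials: float | None = None
    untrained_transfer: float = 0.3
    error_rate: object = None
    n_residual_rows: int = 200
    n_repetitions: int = 6
    n_rest_periods: int = 5
    rest_duration_s: float = 10.0
    trial_prep_s: float = 1.0
    trial_exec_s: float = 3.5
    trial_iti_s: float = 0.5
    tr_s: float = 1.0
    baseline: float = 100.0
    ts_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_runs <= 0:
            raise ValueError("n_runs must be positive")
        if self.n_repetitions % 2 != 0:
            raise ValueError("n_repetitions must be even (paired executions)")
        if not self.mt_start_s > self.mt_end_s > 0:
            raise ValueError("need mt_start_s > mt_end_s > 0")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")
        np.asarray(self.session_correlations(TRAINED))  # validates PSD
        np.asarray(self.session_correlations(UNTRAINED))
        for t in (TRAINED, UNTRAINED):
            sv = self.signal_variances(t)
            if np.any(sv < 0):
                raise ValueError("signal_var must be >= 0")
        er = self.error_rates()
        if np.any(er < 0) or np.any(er > 1):
            raise ValueError("error_rate must lie in [0, 1]")

    # -- derived design constants -------------------------------------
    @property
    def n_conditions(self) -> int:
        return 2 * self.n_sequences_per_type

    @property
    def trial_duration_s(self) -> float:
        return self.trial_prep_s + self.trial_exec_s + self.trial_iti_s

    @property
    def conditions(self) -> list[int]:
        return list(range(self.n_conditions))

    def sequence_type_map(self) -> dict:
        k = self.n_sequences_per_type
        return {c: (TRAINED if c < k else UNTRAINED) for c in self.conditions}

    # -- parameter resolution -----------------------------------------
    def session_correlations(self, seq_type: str) -> np.ndarray:
        r = self.r_true
        S = self.n_sessions
        if r is None:
            base = DEFAULT_R_TRUE[seq_type]
            if S <= base.shape[0]:
                mat = base[:S, :S].copy()
            else:
                raise ValueError(
                    "default r_true covers 4 sessions; pass r_true explicitly")
        elif np.isscalar(r):
            mat = np.full((S, S), float(r))
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(r[seq_type], dtype=float)
            if mat.shape != (S, S):
                raise ValueError("r_true matrix must be n_sessions x n_sessions")
        if np.any(np.abs(mat) > 1) or not np.allclose(mat, mat.T):
            raise ValueError("correlations must be symmetric and in [-1, 1]")
        w = np.linalg.eigvalsh(mat)
        if w.min() < -1e-10:
            raise ValueError(
                f"cross-session correlation matrix for {seq_type!r} is not "
                f"positive semi-definite (min eigenvalue {w.min():.3g})")
        return mat

    def signal_variances(self, seq_type: str) -> np.ndarray:
        sv = self.signal_var
        if isinstance(sv, dict):
            sv = sv[seq_type]
        sv = np.asarray(sv, dtype=float)
        if sv.ndim == 0:
            sv = np.full(self.n_sessions, float(sv))
        if sv.shape != (self.n_sessions,):
            raise ValueError("signal_var must be scalar or per-session")
        return sv

    def error_rates(self) -> np.ndarray:
        er = self.error_rate
        if er is None:
            if self.n_sessions <= DEFAULT_ERROR_RATE.shape[0]:
                return DEFAULT_ERROR_RATE[: self.n_sessions]
            raise ValueError("default error_rate covers 4 sessions")
        er = np.asarray(er, dtype=float)
        if er.ndim == 0:
            return np.full((self.n_sessions, 2), float(er))
        if er.shape != (self.n_sessions, 2):
            raise ValueError("error_rate must be scalar or (n_sessions, 2)")
        return er

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *stream])


# stream ids for independent random substreams
_DESIGN, _PATTERNS, _ESTIMATES, _TIMESERIES, _BEHAVIOR = range(1, 6)


def make_design(config: SimConfig, session: int = 0, subject: int = 0,
                conditions=None) -> pd.DataFrame:
    """Trial table of one subject-session: randomized paired repetitions.

    Each condition appears ``n_repetitions`` times per run as back-to-back
    pairs whose order is shuffled; ``n_rest_periods`` rest periods of
    ``rest_duration_s`` are inserted at uniformly random trial boundaries.
    Onsets restart at 0 in every run.
    """
    if conditions is None:
        conditions = config.conditions
    seq_type = config.sequence_type_map()
    rng = config.rng(_DESIGN, subject, session)
    rows = []
    dur = config.trial_duration_s
    for run in range(config.n_runs):
        blocks = [c for c in conditions for _ in range(config.n_repetitions // 2)]
        order = rng.permutation(len(blocks))
        trial_conds = []
        for b in order:
            trial_conds.extend([blocks[b], blocks[b]])  # twice in a row
        n_trials = len(trial_conds)
        rest_after = np.zeros(n_trials + 1)
        if config.n_rest_periods > 0:
            if n_trials < 2:
                raise ValueError("cannot place rests with fewer than 2 trials")
            spots = rng.choice(n_trials - 1, size=config.n_rest_periods,
                               replace=config.n_rest_periods > n_trials - 1) + 1
            for s in spots:
                rest_after[s] += config.rest_duration_s
        t = 0.0
        for i, c in enumerate(trial_conds):
            t += rest_after[i]
            rows.append({
                "subject": subject, "session": session, "run": run,
                "trial_index": i, "condition_id": c,
                "sequence_type": seq_type.get(c, TRAINED),
                "onset_s": t, "duration_s": dur,
            })
            t += dur
    return pd.DataFrame(rows)


def _session_factor(corr: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Factor A with A A' = diag(sd) corr diag(sd); PSD-safe (eigh)."""
    sd = np.sqrt(variances)
    cov = corr * np.outer(sd, sd)
    w, U = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def make_true_patterns(config: SimConfig) -> dict:
    """True per-sequence patterns: ``{subject: (session, condition, voxel)}``.

    For each sequence independently, the stack of its session patterns is
    zero-mean multivariate normal across sessions with per-session variance
    ``signal_var`` and session-pair correlation ``r_true``; sequences and
    voxels are mutually independent.
    """
    S, V = config.n_sessions, config.n_voxels
    factors = {
        t: _session_factor(config.session_correlations(t),
                           config.signal_variances(t))
        for t in (TRAINED, UNTRAINED)
    }
    seq_type = config.sequence_type_map()
    out = {}
    for subj in range(config.n_subjects):
        rng = config.rng(_PATTERNS, subj)
        pats = np.empty((S, config.n_conditions, V))
        for c in config.conditions:
            z = rng.standard_normal((S, V))
            pats[:, c, :] = factors[seq_type[c]] @ z
        out[subj] = pats
    return out


def _spatial_noise(rng, shape, config: SimConfig) -> np.ndarray:
    """Noise with covariance noise_var * Sigma_voxel over the last axis."""
    spec = config.voxel_cov
    z = rng.standard_normal(shape)
    if spec == "identity":
        out = z
    else:
        kind, rho = spec
        if kind != "ar1":
            raise ValueError(f"unknown voxel_cov {spec!r}")
        out = np.empty_like(z)
        out[..., 0] = z[..., 0]
        a = np.sqrt(1.0 - rho ** 2)
        for v in range(1, shape[-1]):
            out[..., v] = rho * out[..., v - 1] + a * z[..., v]
    return np.sqrt(config.noise_var) * out


def make_run_estimates(true_patterns: dict, config: SimConfig) -> dict:
    """Noisy run-level activation estimates per subject and session.

    Returns ``{(subject, session): PatternDataset}``. Each run's condition
    estimate is the true pattern plus noise with covariance ``noise_var *
    Sigma_voxel``; residual matrices (``n_residual_rows`` per run) follow
    the same noise law and carry ``dof`` equal to their row count, so
    prewhitening can estimate the noise covariance.
    """
    C, V, R = config.n_conditions, config.n_voxels, config.n_runs
    seq_type = config.sequence_type_map()
    out = {}
    for subj, pats in true_patterns.items():
        for sess in range(pats.shape[0]):
            rng = config.rng(_ESTIMATES, subj, sess)
            noise = _spatial_noise(rng, (R, C, V), config)
            data = pats[sess][None, :, :] + noise
            n_res = config.n_residual_rows * R
            residuals = _spatial_noise(rng, (n_res, V), config)
            out[(subj, sess)] = PatternDataset(
                data=data.reshape(R * C, V),
                condition_ids=np.tile(np.arange(C), R),
                partition_ids=np.repeat(np.arange(R), C),
                sequence_type=seq_type,
                session=sess,
                residuals=residuals,
                dof=n_res,
            )
    return out


def make_timeseries(trials: pd.DataFrame, true_pattern: np.ndarray,
                    config: SimConfig, subject: int = 0, session: int = 0):
    """BOLD-like time series from a trial table and true condition patterns.

    ``true_pattern`` is ``(n_conditions, n_voxels)`` for this session. The
    series is baseline + sum over conditions of (boxcar (x) HRF) times the
    condition's pattern + white noise, sampled at ``tr_s``. Returns
    ``(timeseries: {run: (T, V)}, events: DataFrame, true_betas)``; the
    regressor normalization makes the injected pattern the ground-truth
    GLM beta.
    """
    from .glm import HRFSpec, build_design, hrf

    kernel = hrf(HRFSpec(dt_s=0.1))
    rng = config.rng(_TIMESERIES, subject, session)
    series = {}
    events = trials.rename(columns={
        "onset_s": "onset", "duration_s": "duration",
        "condition_id": "trial_type"})[
        ["run", "onset", "duration", "trial_type"]
        + (["is_error"] if "is_error" in trials.columns else [])
    ].copy()
    conds = sorted(events["trial_type"].unique().tolist())
    B = np.asarray(true_pattern, dtype=float)
    for run, ev in events.groupby("run"):
        end = (ev["onset"] + ev["duration"]).max()
        n_t = int(np.ceil(end / config.tr_s)) + 8  # trailing rest
        X, order = build_design(ev, kernel, n_t, config.tr_s, 0.1, conds)
        Y = X[:, :-1] @ B[np.asarray(order, dtype=int)] + config.baseline
        Y = Y + config.ts_noise_sd * rng.standard_normal(Y.shape)
        series[run] = Y
    return series, events, B


def make_behavior(config: SimConfig) -> pd.DataFrame:
    """Behavioral trial table with movement times and error flags.

    Trained-sequence movement time decays exponentially from ``mt_start_s``
    toward ``mt_end_s`` over a subject's cumulative scanner trials;
    untrained sequences follow the same curve scaled to
    ``untrained_transfer`` of the trained improvement. Trial-wise noise is
    lognormal with unit mean; errors are i.i.d. Bernoulli at the
    per-session, per-type rate.
    """
    frames = []
    er = config.error_rates()
    trials_per_sess = (config.n_runs * config.n_conditions
                       * config.n_repetitions)
    total = config.n_sessions * trials_per_sess
    tau = config.mt_tau_trials if config.mt_tau_trials is not None else total / 5.0
    span = config.mt_start_s - config.mt_end_s
    sig = config.mt_noise_sigma
    for subj in range(config.n_subjects):
        rng = config.rng(_BEHAVIOR, subj)
        counter = 0
        for sess in range(config.n_sessions):
            tab = make_design(config, session=sess, subject=subj)
            idx = counter + np.arange(len(tab))
            counter += len(tab)
            learned = span * (1.0 - np.exp(-idx / tau))
            mt_trained = config.mt_start_s - learned
            mt_untrained = config.mt_start_s - config.untrained_transfer * learned
            is_trained = (tab["sequence_type"] == TRAINED).to_numpy()
            mt = np.where(is_trained, mt_trained, mt_untrained)
            if sig > 0:
                mt = mt * np.exp(sig * rng.standard_normal(len(mt))
                                 - 0.5 * sig ** 2)
            rate = np.where(is_trained, er[sess, 0], er[sess, 1])
            tab = tab.copy()
            tab["movement_time_s"] = mt
            tab["is_error"] = rng.random(len(tab)) < rate
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def simulate_study(config: SimConfig, with_timeseries: bool = False) -> dict:
    """Generate the whole synthetic study.

    Returns a dict with ``config``, ``true_patterns``, ``datasets``
    (``{(subject, session): PatternDataset}``), ``behavior`` and, when
    requested, ``timeseries`` for subject 0 of each session.
    """
    true_patterns = make_true_patterns(config)
    datasets = make_run_estimates(true_patterns, config)
    behavior = make_behavior(config)
    out = {"config": config, "true_patterns": true_patterns,
           "datasets": datasets, "behavior": behavior}
    if with_timeseries:
        ts = {}
        for sess in range(config.n_sessions):
            trials = behavior[(behavior["subject"] == 0)
                              & (behavior["session"] == sess)]
            ts[sess] = make_timeseries(trials, true_patterns[0][sess],
                                       config, subject=0, session=sess)
        out["timeseries"] = ts
    return out
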