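"""Fixed-correlation pattern component models (PCM) across sessions.

A sequence's true activity pattern in two scanning sessions is modelled as
a zero-mean Gaussian process over voxels with second-moment matrix

    G(r, a1, a2) = [[ exp(a1) I_k,            r exp((a1+a2)/2) I_k ],
                    [ r exp((a1+a2)/2) I_k,   exp(a2) I_k          ]]

so ``r`` is the true cross-session correlation of sequence-specific
patterns, and ``exp(a1), exp(a2)`` are per-session signal variances shared
across the k sequences. Observed run-level patterns add per-session
Gaussian noise ``exp(s_m)``. Because signal and noise are modelled
explicitly, comparing the maximized (type-II) marginal likelihood across a
grid of fixed ``r`` values estimates pattern stability without the
noise-induced downward bias of sample correlations: if the data carry no
signal, the evidence curve is flat rather than peaked at low ``r``.

Model evidence per subject is the log-likelihood maximized over
``(a1, a2, s1, s2)``; differences of log evidences are read as log-Bayes
factors. Group inference selects best-fitting models on n-1 subjects and
evaluates them on the left-out subject, avoiding double-dipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .datasets import PatternDataset

_LOG_LB = math.log(1e-8)  # lower bound for log-variances, keeps G and V PD
_LOG2PI = math.log(2.0 * math.pi)


def build_G(r: float, a1: float, a2: float, k: int) -> np.ndarray:
    """Second-moment matrix of k sequences in two sessions.

    Parameters are the correlation ``r`` and per-session *log* signal
    variances ``a1, a2``. The off-diagonal blocks are
    ``r * exp((a1+a2)/2) * I_k`` so that the implied correlation is exactly
    ``r`` for any signal variances.
    """
    v1, v2 = math.exp(a1), math.exp(a2)
    c = r * math.sqrt(v1 * v2)
    I = np.eye(k)
    return np.block([[v1 * I, c * I], [c * I, v2 * I]])


def pcm_loglik(Y: np.ndarray, Z: np.ndarray, G: np.ndarray, noise) -> float:
    """Marginal log-likelihood of patterns under a pattern-component model.

    Each voxel (column of ``Y``, shape ``(N, P)``) is an independent draw
    ``y ~ N(0, V)`` with ``V = Z G Z' + diag(noise)``; ``noise`` is a
    scalar or per-row variance vector. Returns

        L = -(N P / 2) ln 2pi - (P / 2) ln|V| - 1/2 tr(V^-1 Y Y').

    Evaluated through the rank decomposition of ``Z G Z'`` (matrix
    determinant lemma + Woodbury), so the cost scales with ``rank(G)``
    rather than ``N``.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    N, P = Y.shape
    d = np.broadcast_to(np.asarray(noise, dtype=float), (N,)).copy()
    if np.any(d <= 0):
        raise ValueError("noise variances must be positive")
    w, U = linalg.eigh(np.asarray(G, dtype=float))
    if w.min() < -1e-10 * max(abs(w).max(), 1.0):
        raise ValueError("G must be positive semi-definite")
    pos = w > max(w.max(), 0.0) * 1e-14
    A = Z @ (U[:, pos] * np.sqrt(w[pos]))  # N x rank, V = diag(d) + A A'
    Ad = A / d[:, None]
    B = np.eye(A.shape[1]) + A.T @ Ad
    cB, low = linalg.cho_factor(B, lower=True)
    logdet = float(np.sum(np.log(d)) + 2.0 * np.sum(np.log(np.diag(cB))))
    Yd = Y / d[:, None]
    quad = float(np.sum(Y * Yd))
    W = A.T @ Yd
    quad -= float(np.sum(W * linalg.cho_solve((cB, low), W)))
    return -0.5 * N * P * _LOG2PI - 0.5 * P * logdet - 0.5 * quad


@dataclass(frozen=True)
class CorrelationModelFamily:
    """Grid of fixed-correlation models spanning [0, 1] inclusive.

    The default follows the study: 30 correlation values in equal steps
    (step 1/29), each model leaving per-session log signal variances
    ``(a1, a2)`` and log noise variances ``(s1, s2)`` free.
    """

    n_models: int = 30
    r_min: float = 0.0
    r_max: float = 1.0
    k: int = 6

    def __post_init__(self):
        if self.n_models < 2 or not 0 <= self.r_min < self.r_max <= 1:
            raise ValueError("invalid correlation grid")

    @property
    def r_grid(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_max, self.n_models)


# ---------------------------------------------------------------------
# Data preparation: two sessions of one sequence type, run intercepts
# removed as fixed effects by projection onto within-run contrasts.
# ---------------------------------------------------------------------

def _contrast_basis(k: int) -> np.ndarray:
    """Orthonormal (k x k-1) basis of the space orthogonal to the run mean."""
    A = np.eye(k) - np.ones((k, k)) / k
    U, s, _ = np.linalg.svd(A)
    return U[:, : k - 1]


@dataclass
class PCMData:
    """Sufficient statistics of one subject's two-session pattern data.

    ``Y`` holds run-intercept-free contrast patterns (rows grouped by
    session, contrast dimension and run), ``Z`` the pseudo-condition
    indicator, ``session_of_row`` the session of every row. ``rss`` (per
    session), ``M2`` (2 x 2 cross-session second moment of run-mean
    contrasts, scaled by sqrt(n_runs)) and the design counts are the
    sufficient statistics the fast likelihood uses.
    """

    Y: np.ndarray
    Z: np.ndarray
    session_of_row: np.ndarray
    n_runs: int
    q: int  # contrast dimensions per session (= k - 1)
    P: int
    rss: np.ndarray  # (2,)
    M2: np.ndarray  # (2, 2)

    @property
    def N(self) -> int:
        return self.Y.shape[0]


def prepare_session_pair(ds1: PatternDataset, ds2: PatternDataset,
                         conditions=None) -> PCMData:
    """Project a two-session dataset pair into the PCM analysis space.

    Both datasets must share the condition set (after optional restriction
    to ``conditions``, e.g. the 6 trained sequences) and be balanced. Run
    intercepts are removed as fixed effects: within every run, the k
    condition patterns are projected onto k-1 orthonormal contrasts, which
    leaves the noise i.i.d. and turns the scaled-identity G blocks into
    scaled identities of size k-1.
    """
    if conditions is not None:
        ds1 = ds1.subset_conditions(conditions)
        ds2 = ds2.subset_conditions(conditions)
    if ds1.conditions != ds2.conditions:
        raise ValueError("session datasets must share their condition set")
    if ds1.n_voxels != ds2.n_voxels:
        raise ValueError("session datasets must share their voxel space")
    k = len(ds1.conditions)
    if k < 2:
        raise ValueError("need at least 2 conditions")
    Q = _contrast_basis(k)
    q = k - 1
    P = ds1.n_voxels
    blocks, sess_rows, z_rows = [], [], []
    n_runs = len(ds1.partitions)
    if len(ds2.partitions) != n_runs:
        raise ValueError("sessions must have the same number of runs")
    for m, ds in enumerate((ds1, ds2)):
        for t, part in enumerate(ds.partitions):
            u = Q.T @ ds.partition_matrix(part)  # (q, P)
            blocks.append(u)
            sess_rows.extend([m] * q)
            z_rows.extend(m * q + np.arange(q))
    Y = np.vstack(blocks)
    Z = np.zeros((Y.shape[0], 2 * q))
    Z[np.arange(Y.shape[0]), z_rows] = 1.0
    session_of_row = np.asarray(sess_rows)
    # sufficient statistics
    rss = np.zeros(2)
    W = np.zeros((2, q, P))
    for m, ds in enumerate((ds1, ds2)):
        stack = np.stack([Q.T @ ds.partition_matrix(p) for p in ds.partitions])
        mean = stack.mean(axis=0)
        rss[m] = float(((stack - mean) ** 2).sum())
        W[m] = math.sqrt(n_runs) * mean
    M2 = np.einsum("mqp,nqp->mn", W, W)
    return PCMData(Y=Y, Z=Z, session_of_row=session_of_row, n_runs=n_runs,
                   q=q, P=P, rss=rss, M2=M2)


# ---------------------------------------------------------------------
# Fast reduced likelihood: G = Sigma2 (x) I_q and per-session iid noise
# collapse the model onto 2x2 algebra over sufficient statistics.
# ---------------------------------------------------------------------

def _reduced_negloglik(theta, r, data: PCMData):
    """(-L, -grad) of the reduced likelihood; pure-scalar 2x2 algebra."""
    a1, a2, s1, s2 = theta
    q, n, P = data.q, data.n_runs, data.P
    e_a1, e_a2 = math.exp(a1), math.exp(a2)
    e_s1, e_s2 = math.exp(s1), math.exp(s2)
    c = r * math.sqrt(e_a1 * e_a2)
    # Wn = n * Sigma2 + diag(noise)
    w11 = n * e_a1 + e_s1
    w22 = n * e_a2 + e_s2
    w12 = n * c
    det = w11 * w22 - w12 * w12
    if det <= 0 or w11 <= 0:
        return 1e12, np.zeros(4)
    i11, i22, i12 = w22 / det, w11 / det, -w12 / det
    m11 = data.M2[0, 0]
    m22 = data.M2[1, 1]
    m12 = data.M2[0, 1]
    rss1, rss2 = data.rss
    N = data.N
    tr_wim = i11 * m11 + i22 * m22 + 2.0 * i12 * m12
    L = (-0.5 * N * P * _LOG2PI
         - 0.5 * q * P * math.log(det)
         - 0.5 * tr_wim
         - 0.5 * q * (n - 1) * P * (s1 + s2)
         - 0.5 * (rss1 / e_s1 + rss2 / e_s2))
    # T = Wi M2 Wi (symmetric 2x2)
    t11 = i11 * (i11 * m11 + i12 * m12) + i12 * (i11 * m12 + i12 * m22)
    t12 = i11 * (i12 * m11 + i22 * m12) + i12 * (i12 * m12 + i22 * m22)
    t22 = i12 * (i12 * m11 + i22 * m12) + i22 * (i12 * m12 + i22 * m22)

    def dL(d11, d12, d22, extra=0.0):
        tr_wi = i11 * d11 + i22 * d22 + 2.0 * i12 * d12
        tr_t = t11 * d11 + t22 * d22 + 2.0 * t12 * d12
        return -0.5 * q * P * tr_wi + 0.5 * tr_t + extra

    half_c = 0.5 * n * c
    g_a1 = dL(n * e_a1, half_c, 0.0)
    g_a2 = dL(0.0, half_c, n * e_a2)
    g_s1 = dL(e_s1, 0.0, 0.0,
              extra=-0.5 * q * (n - 1) * P + 0.5 * rss1 / e_s1)
    g_s2 = dL(0.0, 0.0, e_s2,
              extra=-0.5 * q * (n - 1) * P + 0.5 * rss2 / e_s2)
    return -L, -np.array([g_a1, g_a2, g_s1, g_s2])


def _moment_start(data: PCMData) -> np.ndarray:
    q, n, P = data.q, data.n_runs, data.P
    s = np.log(np.maximum(data.rss / (q * (n - 1) * P), 1e-6))
    a = np.empty(2)
    for m in range(2):
        sig = (data.M2[m, m] / (q * P) - math.exp(s[m])) / n
        a[m] = math.log(max(sig, 1e-4))
    return np.array([a[0], a[1], s[0], s[1]])


def fit_model(data: PCMData, r: float, n_restarts: int = 2):
    """Maximize the marginal likelihood of one correlation model.

    Gradient-based ascent (L-BFGS-B) in log-variance space with analytic
    derivatives, restarted from a moment-based and a default start; the
    best run wins. Log-variances are bounded below at ln(1e-8) to keep G
    and V positive definite.

    Returns ``(loglik, theta_hat, converged)``.
    """
    starts = [_moment_start(data), np.zeros(4)]
    for i in range(2, n_restarts):
        starts.append(_moment_start(data) + 0.5 * np.array(
            [((i * 37 + j * 11) % 7 - 3) / 3.0 for j in range(4)]))
    bounds = [(_LOG_LB, 25.0)] * 4
    best = None
    for x0 in starts[:max(n_restarts, 2)]:
        res = optimize.minimize(
            _reduced_negloglik, np.clip(x0, _LOG_LB, 25.0), args=(r, data),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), best.x.copy(), bool(best.success)


def loglik_at(data: PCMData, r: float, theta) -> float:
    """Reduced-likelihood evaluation at fixed parameters (no fitting)."""
    nll, _ = _reduced_negloglik(np.asarray(theta, dtype=float), r, data)
    return -float(nll)


# ---------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------

@dataclass
class CorrelationPCMResults:
    """Per-subject model evidences for a correlation-model family.

    ``loglik[i, j]`` is subject i's maximized (type-II) log-likelihood
    under correlation ``family.r_grid[j]``; ``rel_loglik`` subtracts each
    subject's mean over models, so rows sum to 0 and differences read as
    log-Bayes factors.
    """

    family: CorrelationModelFamily
    loglik: np.ndarray
    theta: np.ndarray
    converged: np.ndarray
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        if not self.subjects:
            self.subjects = list(range(self.loglik.shape[0]))

    @property
    def rel_loglik(self) -> np.ndarray:
        return self.loglik - self.loglik.mean(axis=1, keepdims=True)

    def group_curve(self):
        """Mean relative log-likelihood across subjects and its SEM."""
        rel = self.rel_loglik
        mean = rel.mean(axis=0)
        sem = rel.std(axis=0, ddof=1) / math.sqrt(rel.shape[0])
        return mean, sem

    @property
    def best_r(self) -> float:
        """Grid correlation maximizing the group curve (lower r on ties)."""
        mean, _ = self.group_curve()
        return float(self.family.r_grid[int(np.argmax(mean))])

    def summary(self) -> str:
        mean, sem = self.group_curve()
        j = int(np.argmax(mean))
        lines = [
            "Correlation PCM results",
            "=" * 52,
            f"subjects:                  {self.loglik.shape[0]}",
            f"models (r grid):           {self.family.n_models} on "
            f"[{self.family.r_min:g}, {self.family.r_max:g}]",
            f"winning correlation:       r = {self.family.r_grid[j]:.3f}",
            f"evidence at winner:        {mean[j]:.2f} +/- {sem[j]:.2f} "
            "(log-units vs model mean)",
            f"evidence range (max-min):  {mean.max() - mean.min():.2f}",
            f"converged fits:            {int(self.converged.sum())}/"
            f"{self.converged.size}",
        ]
        return "\n".join(lines)

    def plot_evidence(self, ax=None, label=None, color=None):
        """Group evidence curve with between-subject standard error."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mean, sem = self.group_curve()
        r = self.family.r_grid
        ax.plot(r, mean, color=color, label=label)
        ax.fill_between(r, mean - sem, mean + sem, alpha=0.3, color=color)
        ax.set_xlabel("model correlation r")
        ax.set_ylabel("log-likelihood vs model mean")
        return ax


class CorrelationPCM:
    """Fixed-correlation PCM fitted to a group of two-session datasets.

    Parameters
    ----------
    data
        Per-subject data: a list of :class:`PCMData`, or of
        ``(session_a, session_b)`` :class:`PatternDataset` pairs (then
        ``conditions`` selects the sequences entering the model, e.g. the
        trained set).
    family
        Correlation-model grid; defaults to 30 models on [0, 1].
    conditions
        Condition subset used when building :class:`PCMData` from dataset
        pairs.
    """

    def __init__(self, data, family: CorrelationModelFamily | None = None,
                 conditions=None):
        prepared = []
        for item in data:
            if isinstance(item, PCMData):
                prepared.append(item)
            else:
                ds1, ds2 = item
                prepared.append(prepare_session_pair(ds1, ds2, conditions))
        if len(prepared) < 1:
            raise ValueError("need at least one subject")
        self.data = prepared
        self.family = family if family is not None else CorrelationModelFamily()

    def fit(self, n_restarts: int = 2) -> CorrelationPCMResults:
        S, M = len(self.data), self.family.n_models
        loglik = np.empty((S, M))
        theta = np.empty((S, M, 4))
        conv = np.empty((S, M), dtype=bool)
        for i, d in enumerate(self.data):
            for j, r in enumerate(self.family.r_grid):
                loglik[i, j], theta[i, j], conv[i, j] = fit_model(
                    d, float(r), n_restarts)
        return CorrelationPCMResults(family=self.family, loglik=loglik,
                                     theta=theta, converged=conv)


def evidence_curves(data, family: CorrelationModelFamily | None = None,
                    conditions=None) -> CorrelationPCMResults:
    """Fit every subject under every correlation model (functional form)."""
    return CorrelationPCM(data, family=family, conditions=conditions).fit()


# ---------------------------------------------------------------------
# Group inference
# ---------------------------------------------------------------------

def _fold_selection(loglik: np.ndarray, leave_out: int) -> int:
    """Index of the best model on all subjects except ``leave_out``
    (summed log-likelihood); ties take the lower grid index."""
    mask = np.ones(loglik.shape[0], dtype=bool)
    mask[leave_out] = False
    total = loglik[mask].sum(axis=0)
    return int(np.argmax(total))


def crossval_group_test(result_a: CorrelationPCMResults,
                        result_b: CorrelationPCMResults):
    """Crossvalidated comparison of best-fitting correlations.

    For every left-out subject i, the best model of condition set A
    (``r*_A``) and of set B (``r*_B``) are chosen on the remaining n-1
    subjects; the out-of-sample log-Bayes factor

        delta_i = loglik_A(i, r*_B) - loglik_A(i, r*_A)

    is recorded, and a one-sided paired t-test asks whether A's data are
    better explained by A's own best correlation than by B's (H1: mean
    delta < 0, i.e. the two correlations genuinely differ). When every
    fold selects identical models for A and B the statistic is degenerate
    and ``(t, p) = (0, 1)`` is returned.

    Returns ``(delta, t, p)``.
    """
    if result_a.loglik.shape != result_b.loglik.shape:
        raise ValueError("results must share subjects and model grid")
    n = result_a.loglik.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    delta = np.empty(n)
    for i in range(n):
        ja = _fold_selection(result_a.loglik, i)
        jb = _fold_selection(result_b.loglik, i)
        delta[i] = result_a.loglik[i, jb] - result_a.loglik[i, ja]
    if np.allclose(delta, 0.0):
        return delta, 0.0, 1.0
    t, p = stats.ttest_1samp(delta, 0.0, alternative="less")
    return delta, float(t), float(p)


def winning_model_map(results_by_location: dict,
                      evidence_threshold: float = 1.0) -> dict:
    """Winning correlation per location, masked by evidence strength.

    For every location (e.g. cortical tessel), the winning ``r`` is the
    argmax of the group-mean relative log-likelihood; locations where the
    winning model beats the worst-fitting model by no more than
    ``evidence_threshold`` log-units (log-Bayes factor) come back NaN.
    """
    out = {}
    for loc, res in results_by_location.items():
        mean, _ = res.group_curve()
        j = int(np.argmax(mean))
        if mean[j] - mean.min() > evidence_threshold:
            out[loc] = float(res.family.r_grid[j])
        else:
            out[loc] = float("nan")
    return out
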