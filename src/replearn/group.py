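"""Group-level statistics: t-tests, within-subject ANOVA, sign-flip FWE.

The permutation test implements max-statistic family-wise error control
under a symmetric null: each permutation flips the sign of every subject's
contrast independently, the group t-map is recomputed and thresholded at
the uncorrected level, and the map-wise peak |t| and largest
suprathreshold cluster size enter the null distributions. The observed
statistic is always counted in its own null, so FWE p-values are bounded
below by 1 / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GroupMap


def ttest(values, mu0: float = 0.0, sides: int = 2, paired_with=None):
    """One-sample (or paired) t-test with dof = n - 1.

    Returns ``(t, dof, p)``. ``sides`` is 1 or 2; the one-sided test is
    against the alternative mean > mu0 (flip the sign of the data for the
    other direction). ``paired_with`` subtracts a second sample first.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        x = x - np.asarray(paired_with, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    dof = n - 1
    if sides == 2:
        p = 2.0 * stats.t.sf(abs(t), dof)
    elif sides == 1:
        p = stats.t.sf(t, dof)
    else:
        raise ValueError("sides must be 1 or 2")
    return float(t), int(dof), float(p)


def rm_anova2(table: pd.DataFrame, subject: str = "subject",
              factor_a: str = "A", factor_b: str = "B",
              value: str = "value") -> pd.DataFrame:
    """Two-way fully within-subject (repeated-measures) ANOVA.

    Every effect is tested against its interaction with subjects, with
    conventional uncorrected degrees of freedom: for factor A with a
    levels and n subjects, ``F(a-1, (a-1)(n-1))``; likewise for B and
    A x B. The table must be complete and balanced (one value per subject
    x cell). Returns a DataFrame indexed by effect with columns ``F``,
    ``df1``, ``df2``, ``p``.
    """
    piv = table.pivot_table(index=subject, columns=[factor_a, factor_b],
                            values=value, aggfunc="count")
    counts = table.groupby([subject, factor_a, factor_b])[value].count()
    if (counts != 1).any() or piv.isna().any().any():
        raise ValueError("table must contain exactly one value per "
                         "subject x factor cell")
    wide = table.pivot_table(index=subject, columns=[factor_a, factor_b],
                             values=value)
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    n, a, b = wide.shape[0], len(a_levels), len(b_levels)
    vals = wide.to_numpy().reshape(n, a, b)
    grand = vals.mean()
    m_s = vals.mean(axis=(1, 2))
    m_a = vals.mean(axis=(0, 2))
    m_b = vals.mean(axis=(0, 1))
    m_ab = vals.mean(axis=0)
    m_sa = vals.mean(axis=2)
    m_sb = vals.mean(axis=1)
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None] + grand) ** 2).sum()
    ss_sab = ((vals - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None]
               + m_s[:, None, None] + m_a[None, :, None]
               + m_b[None, None, :] - grand) ** 2).sum()
    rows = []
    scale = max(float((vals ** 2).sum()), 1.0)
    for name, ss, df1, ss_err, df2 in (
        (factor_a, ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        (factor_b, ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        (f"{factor_a}:{factor_b}", ss_ab, (a - 1) * (b - 1), ss_sab,
         (a - 1) * (b - 1) * (n - 1)),
    ):
        if ss <= 1e-12 * scale:  # no effect at all: F defined as 0
            F = 0.0
        elif ss_err <= 1e-12 * scale:
            F = np.inf
        else:
            F = (ss / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append((name, F, df1, df2, p))
    out = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
    return out.set_index("effect")


def group_tmap(gmap: GroupMap, contrast=None) -> np.ndarray:
    """One-sample t across subjects at every location.

    ``contrast`` (optional, subjects x locations) is subtracted first,
    turning the test into a paired comparison. Zero-variance locations
    come back NaN (masked).
    """
    x = gmap.data
    if contrast is not None:
        x = x - np.asarray(contrast, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = x.mean(axis=0) / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def label_clusters(above: np.ndarray, adjacency: dict) -> list[int]:
    """Sizes of connected components of the suprathreshold location set.

    ``adjacency`` maps location index -> iterable of neighbor indices.
    Uses sparse connected components over the induced subgraph.
    """
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pos = {int(v): i for i, v in enumerate(idx)}
    rows, cols = [], []
    for v in idx:
        for w in adjacency.get(int(v), ()):
            if int(w) in pos:
                rows.append(pos[int(v)])
                cols.append(pos[int(w)])
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(idx.size, idx.size))
    n_comp, labels = connected_components(graph, directed=False)
    return np.bincount(labels, minlength=n_comp).tolist()


@dataclass
class PermutationResult:
    """Observed and null max statistics of a sign-flip permutation test."""

    observed_peak_t: float
    observed_max_cluster: int
    null_peak_t: np.ndarray
    null_max_cluster: np.ndarray
    fwe_p_peak: float
    fwe_p_cluster: float
    n_permutations: int
    threshold_p: float
    threshold_t: float

    def summary(self) -> str:
        lines = [
            "Sign-flip permutation test",
            "=" * 44,
            f"permutations:         {self.n_permutations}",
            f"uncorrected p:        {self.threshold_p:g} "
            f"(|t| > {self.threshold_t:.3f})",
            f"observed peak |t|:    {self.observed_peak_t:.3f} "
            f"(FWE p = {self.fwe_p_peak:.4f})",
            f"observed max cluster: {self.observed_max_cluster} "
            f"(FWE p = {self.fwe_p_cluster:.4f})",
        ]
        return "\n".join(lines)


def _peak_and_cluster(t: np.ndarray, t_crit: float, adjacency):
    finite = np.nan_to_num(t, nan=0.0)
    peak = float(np.max(np.abs(finite)))
    max_cluster = 0
    if adjacency is not None:
        for above in (finite > t_crit, finite < -t_crit):
            sizes = label_clusters(above, adjacency)
            if sizes:
                max_cluster = max(max_cluster, max(sizes))
    return peak, max_cluster


def signflip_fwe(gmap: GroupMap, threshold_p: float = 0.01,
                 n_perm: int = 1000, seed: int = 0,
                 exhaustive: bool = False) -> PermutationResult:
    """Sign-flip max-statistic permutation FWE test on a group map.

    Each permutation flips every subject's sign independently (uniform
    over the 2^n assignments, sampled with replacement), recomputes the
    group t-map, thresholds it two-sidedly at the uncorrected
    ``threshold_p``, and records the map-wise peak |t| and the largest
    suprathreshold cluster (positive and negative excursions labelled
    separately; requires ``gmap.adjacency``). FWE p-values are
    ``(1 + #{null >= observed}) / (1 + n_perm)``. With
    ``exhaustive=True`` all 2^n - 1 non-identity assignments are
    enumerated instead, which reproduces the exact permutation p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = gmap.data
    n = x.shape[0]
    dof = n - 1
    t_crit = float(stats.t.isf(threshold_p / 2.0, dof))
    obs_t = group_tmap(gmap)
    obs_peak, obs_cluster = _peak_and_cluster(obs_t, t_crit, gmap.adjacency)

    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration is limited to n <= 20")
        signs = np.array([
            [1.0 if (m >> i) & 1 == 0 else -1.0 for i in range(n)]
            for m in range(1, 2 ** n)
        ])
        n_eff = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_eff = n_perm

    null_peak = np.empty(n_eff)
    null_cluster = np.empty(n_eff, dtype=int)
    sqrt_n = np.sqrt(n)
    for b in range(n_eff):
        xb = x * signs[b][:, None]
        sd = xb.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = xb.mean(axis=0) / (sd / sqrt_n)
        t[sd == 0] = 0.0
        null_peak[b], null_cluster[b] = _peak_and_cluster(t, t_crit,
                                                          gmap.adjacency)
    fwe_peak = (1.0 + np.sum(null_peak >= obs_peak)) / (1.0 + n_eff)
    fwe_cluster = (1.0 + np.sum(null_cluster >= obs_cluster)) / (1.0 + n_eff)
    return PermutationResult(
        observed_peak_t=obs_peak,
        observed_max_cluster=int(obs_cluster),
        null_peak_t=null_peak,
        null_max_cluster=null_cluster,
        fwe_p_peak=float(fwe_peak),
        fwe_p_cluster=float(fwe_cluster),
        n_permutations=n_eff,
        threshold_p=threshold_p,
        threshold_t=t_crit,
    )
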