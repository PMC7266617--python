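"""Prewhitening, crossnobis dissimilarities, cosine shifts, MDS, searchlight.

The crossnobis estimator is the cross-validated squared Mahalanobis
distance between condition patterns: contrasts are formed independently in
every pair of imaging runs and their inner products averaged, which makes
the estimator unbiased (expected 0 when two conditions evoke identical true
patterns), so negative values are legitimate. Patterns are multivariately
prewhitened first: scaled by the inverse square root of the voxel noise
covariance estimated from GLM residuals, with shrinkage toward its
diagonal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg

from .datasets import RDM, Neighborhood, PatternDataset, condition_pairs


def _estimate_sigma(residuals: np.ndarray, dof: int) -> np.ndarray:
    residuals = np.asarray(residuals, dtype=float)
    return residuals.T @ residuals / float(dof)


def _auto_shrinkage(residuals: np.ndarray) -> float:
    """Ledoit-Wolf analytic shrinkage intensity (toward a scaled identity
    target), reused here as the intensity for shrinking toward diag(Sigma)."""
    from sklearn.covariance import ledoit_wolf_shrinkage

    x = residuals - residuals.mean(axis=0, keepdims=True)
    return float(ledoit_wolf_shrinkage(x))


def prewhiten(ds: PatternDataset, shrinkage="auto") -> PatternDataset:
    """Multivariate noise normalization of a pattern dataset.

    Estimates the voxel covariance ``Sigma`` from the dataset's GLM
    residuals, regularizes it as ``(1 - lam) Sigma + lam diag(Sigma)``, and
    right-multiplies the data (and residuals) by ``Sigma_reg^(-1/2)``.
    ``shrinkage="auto"`` uses a Ledoit-Wolf analytic intensity;
    ``shrinkage=1`` reduces to univariate standardization by each voxel's
    residual s.d. The intensity used is recorded on the returned dataset as
    ``shrinkage_used``.
    """
    if ds.residuals is None or ds.dof is None or ds.dof <= 0:
        raise ValueError("prewhitening needs residuals with positive dof")
    lam = _auto_shrinkage(ds.residuals) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    if lam == 1.0:
        # univariate standardization: Sigma_reg is diagonal, no eigh needed
        var = np.einsum("ij,ij->j", ds.residuals, ds.residuals) / float(ds.dof)
        if var.min() <= 0:
            raise ValueError("regularized covariance is singular")
        whitener = np.diag(1.0 / np.sqrt(var))
    else:
        sigma = _estimate_sigma(ds.residuals, ds.dof)
        sigma_reg = (1.0 - lam) * sigma + lam * np.diag(np.diag(sigma))
        w, U = linalg.eigh(sigma_reg)
        if w.min() <= 0:
            raise ValueError("regularized covariance is singular")
        whitener = (U / np.sqrt(w)) @ U.T  # Sigma_reg^(-1/2), symmetric
    out = PatternDataset(
        data=ds.data @ whitener,
        condition_ids=ds.condition_ids,
        partition_ids=ds.partition_ids,
        sequence_type=ds.sequence_type,
        session=ds.session,
        residuals=ds.residuals @ whitener,
        dof=ds.dof,
    )
    out.shrinkage_used = lam
    return out


def _partition_stack(ds: PatternDataset, remove_run_mean: bool) -> np.ndarray:
    """(n_partitions, n_conditions, n_voxels) stack, conditions sorted."""
    parts = ds.partitions
    stack = np.stack([ds.partition_matrix(p) for p in parts])
    if remove_run_mean:
        stack = stack - stack.mean(axis=1, keepdims=True)
    return stack


def crossnobis(ds: PatternDataset, remove_run_mean: bool = True,
               n_channels: int | None = None) -> RDM:
    """Cross-validated squared Mahalanobis dissimilarities between conditions.

    For conditions i, j: ``d(i,j) = mean over ordered partition pairs
    (m != n) of (b_i^m - b_j^m)' (b_i^n - b_j^n) / P`` with P the voxel
    count. Expects prewhitened data for Mahalanobis (rather than Euclidean)
    geometry. Run mean patterns are removed within each partition first.
    """
    parts = ds.partitions
    if len(parts) < 2:
        raise ValueError("crossnobis needs at least 2 partitions")
    stack = _partition_stack(ds, remove_run_mean)
    M = len(parts)
    P = n_channels if n_channels is not None else ds.n_voxels
    # sum over m != n of D_m D_n' = (sum D)(sum D)' - sum D_m D_m'
    total = stack.sum(axis=0)
    cross = total @ total.T - np.einsum("mcv,mdv->cd", stack, stack)
    cross /= M * (M - 1) * P
    conds = ds.conditions
    vals = []
    index = {c: i for i, c in enumerate(conds)}
    for a, b in condition_pairs(conds):
        i, j = index[a], index[b]
        vals.append(cross[i, i] + cross[j, j] - cross[i, j] - cross[j, i])
    return RDM(values=np.array(vals), conditions=conds, metric="crossnobis",
               sequence_type=ds.sequence_type)


def naive_distance(ds: PatternDataset, remove_run_mean: bool = True) -> RDM:
    """Non-crossvalidated squared distance between mean condition patterns
    (per voxel). Positively biased by noise; kept as the contrast to the
    unbiased crossnobis estimator."""
    stack = _partition_stack(ds, remove_run_mean)
    means = stack.mean(axis=0)
    conds = ds.conditions
    index = {c: i for i, c in enumerate(conds)}
    vals = []
    for a, b in condition_pairs(conds):
        diff = means[index[a]] - means[index[b]]
        vals.append(float(diff @ diff) / ds.n_voxels)
    return RDM(values=np.array(vals), conditions=conds, metric="euclidean2",
               sequence_type=ds.sequence_type)


def crossnobis_1d(values: pd.DataFrame, residual_var: float | None = None) -> RDM:
    """Crossnobis dissimilarities between per-condition scalars (P = 1).

    ``values`` is a table with columns ``condition``, ``partition``,
    ``value`` (e.g. movement times per sequence and run). Values are
    standardized by the residual s.d. — estimated from the condition x
    partition interaction when ``residual_var`` is not given — and passed
    through the generic crossnobis estimator with one channel.
    """
    piv = values.pivot_table(index="partition", columns="condition",
                             values="value", aggfunc="mean")
    if piv.isna().any().any():
        raise ValueError("unbalanced table: every condition needs a value "
                         "in every partition")
    X = piv.to_numpy()  # partitions x conditions
    if residual_var is None:
        resid = X - X.mean(0, keepdims=True) - X.mean(1, keepdims=True) + X.mean()
        dof = (X.shape[0] - 1) * (X.shape[1] - 1)
        residual_var = float((resid ** 2).sum() / dof) if dof > 0 else 1.0
    if residual_var <= 0:
        residual_var = 1.0  # degenerate: fall back to unwhitened values
    conds = piv.columns.tolist()
    n_p, n_c = X.shape
    ds = PatternDataset(
        data=(X / np.sqrt(residual_var)).reshape(-1, 1),
        condition_ids=np.tile(conds, n_p),
        partition_ids=np.repeat(piv.index.to_numpy(), n_c),
    )
    return crossnobis(ds, remove_run_mean=True, n_channels=1)


def average_rdm(rdm: RDM, sequence_type: dict | None = None) -> dict:
    """Mean dissimilarity overall and within each sequence type.

    For 6 trained + 6 untrained sequences this averages the 15
    within-trained pairs, the 15 within-untrained pairs and all 66 pairs.
    """
    st = sequence_type if sequence_type is not None else rdm.sequence_type
    if st is None:
        raise ValueError("sequence_type labels are required")
    groups = {"within_trained": [], "within_untrained": [], "between": []}
    for (a, b), v in zip(rdm.pairs, rdm.values):
        ta, tb = st[a], st[b]
        if ta == tb == "trained":
            groups["within_trained"].append(v)
        elif ta == tb == "untrained":
            groups["within_untrained"].append(v)
        else:
            groups["between"].append(v)
    out = {k: (float(np.mean(v)) if v else np.nan) for k, v in groups.items()}
    out["overall"] = float(np.mean(rdm.values))
    out["n_pairs"] = {k: len(v) for k, v in groups.items()}
    out["n_pairs"]["overall"] = len(rdm.values)
    return out


def cosine_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine-angle dissimilarity ``1 - a.b / (|a||b|)``.

    Insensitive to overall activation magnitude, so it isolates *relative*
    shifts in the spatial distribution of activity. Range [0, 2].
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine dissimilarity undefined for zero vectors")
    return float(1.0 - (a @ b) / (na * nb))


def cosine_rdm(means: np.ndarray, conditions=None,
               sequence_type: dict | None = None) -> RDM:
    """Pairwise cosine dissimilarities between mean condition patterns."""
    means = np.asarray(means, dtype=float)
    if conditions is None:
        conditions = list(range(means.shape[0]))
    index = {c: i for i, c in enumerate(sorted(conditions))}
    vals = [cosine_dissimilarity(means[index[a]], means[index[b]])
            for a, b in condition_pairs(conditions)]
    return RDM(values=np.array(vals), conditions=list(conditions),
               metric="cosine", sequence_type=sequence_type)


def znormalize_map(values: np.ndarray) -> np.ndarray:
    """Z-score a voxel map (mean 0, s.d. 1 across voxels)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need more than one voxel")
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("constant map cannot be z-normalized")
    return (values - values.mean()) / sd


def classical_mds(rdm, k: int = 2) -> np.ndarray:
    """Torgerson classical MDS of a (squared-)dissimilarity structure.

    ``rdm`` may be an :class:`RDM` or a square matrix of squared
    dissimilarities. Double-centers ``B = -0.5 J D J`` and embeds on the
    top-``k`` eigenvectors; dimensions beyond the positive-eigenvalue count
    are zero-padded with a warning. Coordinates are centered at the origin.
    """
    D = rdm.to_matrix() if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    n = D.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of conditions")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {k - n_pos} "
            "dimension(s) with zeros", stacklevel=2)
    coords = np.zeros((n, k))
    m = min(k, n_pos)
    coords[:, :m] = U[:, :m] * np.sqrt(w[:m])
    return coords


def procrustes_align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate/reflect ``coords`` (about the origin) onto ``reference``.

    Resolves the rotation and sign indeterminacy of classical MDS for
    longitudinal plots by orthogonal Procrustes alignment to a reference
    configuration (no scaling or translation).
    """
    R, _ = linalg.orthogonal_procrustes(coords, reference)
    return coords @ R


def searchlight(ds: PatternDataset, neighborhoods: list[Neighborhood],
                stat_fn) -> dict:
    """Apply ``stat_fn`` within each voxel neighborhood of the dataset.

    ``stat_fn`` receives a :class:`PatternDataset` restricted to the
    neighborhood's voxels (residuals restricted likewise) and its scalar
    result is assigned to the neighborhood's center id.
    """
    out = {}
    V = ds.n_voxels
    for nb in neighborhoods:
        if nb.members.min() < 0 or nb.members.max() >= V:
            raise ValueError(
                f"neighborhood {nb.center_id!r} references invalid voxels")
        sub = PatternDataset(
            data=ds.data[:, nb.members],
            condition_ids=ds.condition_ids,
            partition_ids=ds.partition_ids,
            sequence_type=ds.sequence_type,
            session=ds.session,
            residuals=None if ds.residuals is None
            else ds.residuals[:, nb.members],
            dof=ds.dof,
        )
        out[nb.center_id] = stat_fn(sub)
    return out
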