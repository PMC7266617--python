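"""Core in-memory containers shared by all analysis stages."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

TRAINED = "trained"
UNTRAINED = "untrained"


@dataclass
class PatternDataset:
    """Condition-by-partition activation patterns over voxels.

    The unit of every representational analysis: a ``(n_conditions *
    n_partitions) x n_voxels`` matrix of activation estimates (GLM betas),
    together with the condition and partition (imaging run) label of each
    row. The design must be balanced: every condition appears exactly once
    in every partition.

    Parameters
    ----------
    data
        ``(n_obs, n_voxels)`` activation estimates; rows are
        condition-by-run patterns.
    condition_ids, partition_ids
        Per-row labels, length ``n_obs``.
    sequence_type
        Optional map ``condition_id -> {"trained", "untrained"}``.
    session
        Optional session label (scanning week index).
    residuals
        Optional ``(n_res, n_voxels)`` GLM residuals used to estimate the
        voxel noise covariance for prewhitening.
    dof
        Residual degrees of freedom belonging to ``residuals``.
    """

    data: np.ndarray
    condition_ids: np.ndarray
    partition_ids: np.ndarray
    sequence_type: dict | None = None
    session: object = None
    residuals: np.ndarray | None = None
    dof: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.condition_ids = np.asarray(self.condition_ids)
        self.partition_ids = np.asarray(self.partition_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_obs x n_voxels)")
        n_obs = self.data.shape[0]
        if len(self.condition_ids) != n_obs or len(self.partition_ids) != n_obs:
            raise ValueError("label vectors must match the number of rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("pattern data contain non-finite values")
        self._check_balanced()

    def _check_balanced(self):
        conds = self.conditions
        parts = self.partitions
        counts = {}
        for c, p in zip(self.condition_ids, self.partition_ids):
            counts[(c, p)] = counts.get((c, p), 0) + 1
        for c in conds:
            for p in parts:
                if counts.get((c, p), 0) != 1:
                    raise ValueError(
                        f"unbalanced design: condition {c!r} appears "
                        f"{counts.get((c, p), 0)} times in partition {p!r}"
                    )

    @property
    def conditions(self) -> list:
        return sorted(set(self.condition_ids.tolist()))

    @property
    def partitions(self) -> list:
        return sorted(set(self.partition_ids.tolist()))

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def condition_means(self) -> np.ndarray:
        """Mean pattern per condition (conditions in sorted order)."""
        conds = self.conditions
        out = np.empty((len(conds), self.n_voxels))
        for i, c in enumerate(conds):
            out[i] = self.data[self.condition_ids == c].mean(axis=0)
        return out

    def partition_matrix(self, partition) -> np.ndarray:
        """Condition x voxel matrix of one partition, conditions sorted."""
        mask = self.partition_ids == partition
        sub = self.data[mask]
        order = np.argsort(self.condition_ids[mask], kind="stable")
        return sub[order]

    def subset_conditions(self, keep) -> "PatternDataset":
        keep = set(keep)
        mask = np.array([c in keep for c in self.condition_ids])
        st = None
        if self.sequence_type is not None:
            st = {c: t for c, t in self.sequence_type.items() if c in keep}
        return PatternDataset(
            data=self.data[mask],
            condition_ids=self.condition_ids[mask],
            partition_ids=self.partition_ids[mask],
            sequence_type=st,
            session=self.session,
            residuals=self.residuals,
            dof=self.dof,
        )


def condition_pairs(conditions) -> list[tuple]:
    """Unordered condition pairs in fixed lexicographic order.

    This ordering is the contract for :class:`RDM.values`; it is stable
    across the package so RDM files are comparable.
    """
    return list(itertools.combinations(sorted(conditions), 2))


@dataclass
class RDM:
    """Vector of pairwise dissimilarities over conditions.

    ``values[k]`` corresponds to ``condition_pairs(conditions)[k]``
    (lexicographic pair order). Crossnobis entries are unbiased and may be
    negative; cosine entries lie in [0, 2].
    """

    values: np.ndarray
    conditions: list
    metric: str = "crossnobis"
    sequence_type: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.conditions = list(self.conditions)
        n = len(self.conditions)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"RDM for {n} conditions needs {n*(n-1)//2} values, "
                f"got {self.values.shape}"
            )

    @property
    def pairs(self) -> list[tuple]:
        return condition_pairs(self.conditions)

    def to_matrix(self) -> np.ndarray:
        """Symmetric dissimilarity matrix with zero diagonal."""
        n = len(self.conditions)
        index = {c: i for i, c in enumerate(sorted(self.conditions))}
        mat = np.zeros((n, n))
        for (a, b), v in zip(self.pairs, self.values):
            mat[index[a], index[b]] = v
            mat[index[b], index[a]] = v
        return mat


@dataclass
class Neighborhood:
    """A searchlight region: a center id plus member voxel indices."""

    center_id: object
    members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=int)
        if self.members.size == 0:
            raise ValueError(f"neighborhood {self.center_id!r} is empty")


@dataclass
class GroupMap:
    """Subjects x locations statistic matrix for group inference.

    ``adjacency`` maps a location index to the indices of its neighbors and
    is required for cluster-level permutation statistics.
    """

    data: np.ndarray
    location_ids: list | None = None
    adjacency: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("GroupMap data must be subjects x locations")
        if self.location_ids is None:
            self.location_ids = list(range(self.data.shape[1]))
        if len(self.location_ids) != self.data.shape[1]:
            raise ValueError("location_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]
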