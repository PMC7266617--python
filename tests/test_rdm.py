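"""Prewhitening, crossnobis estimator, cosine shifts, MDS, searchlight."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import replearn as rl
from replearn.datasets import condition_pairs
from replearn.rdm import naive_distance, procrustes_align
from conftest import random_pattern_dataset


def crossnobis_oracle(ds, n_channels=None):
    """Independent double-loop fold-pair estimator with run-mean removal."""
    parts = ds.partitions
    conds = ds.conditions
    P = n_channels if n_channels is not None else ds.n_voxels
    mats = {}
    for p in parts:
        m = ds.partition_matrix(p)
        mats[p] = m - m.mean(axis=0)
    vals = []
    for a, b in condition_pairs(conds):
        ia, ib = conds.index(a), conds.index(b)
        acc, count = 0.0, 0
        for m in parts:
            for n in parts:
                if m == n:
                    continue
                acc += (mats[m][ia] - mats[m][ib]) @ (mats[n][ia] - mats[n][ib])
                count += 1
        vals.append(acc / (count * P))
    return np.array(vals)


class TestPrewhiten:
    def test_lambda1_is_univariate_standardization(self, rng):
        ds = random_pattern_dataset(rng, with_residuals=True)
        out = rl.prewhiten(ds, shrinkage=1.0)
        sd = np.sqrt((ds.residuals ** 2).sum(axis=0) / ds.dof)
        assert np.allclose(out.data, ds.data / sd)

    def test_known_diagonal_covariance_closed_form(self):
        # Sigma = diag(4, 1): pattern (2, 1) -> (1, 1) under lambda = 1
        resid = np.zeros((8, 2))
        resid[:4, 0], resid[4:, 0] = 2.0, -2.0
        resid[:4, 1], resid[4:, 1] = 1.0, -1.0
        ds = rl.PatternDataset(
            data=np.array([[2.0, 1.0], [2.0, 1.0]]),
            condition_ids=[0, 0], partition_ids=[0, 1],
            residuals=resid, dof=8)
        out = rl.prewhiten(ds, shrinkage=1.0)
        assert np.allclose(out.data, 1.0)

    def test_identity_covariance_large_sample_is_noop(self, rng):
        data = rng.standard_normal((6, 30))
        ds = rl.PatternDataset(
            data=data, condition_ids=[0, 1, 2] * 2,
            partition_ids=[0] * 3 + [1] * 3,
            residuals=rng.standard_normal((100_000, 30)), dof=100_000)
        out = rl.prewhiten(ds, shrinkage=0.0)
        assert np.allclose(out.data, data, atol=0.05)
        assert out.shrinkage_used == 0.0

    def test_requires_residuals(self, rng):
        ds = random_pattern_dataset(rng)
        with pytest.raises(ValueError, match="residuals"):
            rl.prewhiten(ds)


class TestCrossnobis:
    def test_identical_patterns_give_zero(self):
        row = np.arange(4.0)  # every condition evokes the same pattern
        ds = rl.PatternDataset(
            data=np.tile(row, (6, 1)), condition_ids=[0, 1, 2] * 2,
            partition_ids=[0] * 3 + [1] * 3)
        assert np.allclose(rl.crossnobis(ds).values, 0.0)

    def test_known_separation_closed_form(self):
        # two conditions differing by a vector of squared norm 8, P = 4 -> d = 2
        diff = np.array([2.0, 2.0, 0.0, 0.0])  # |diff|^2 = 8
        row = np.zeros(4)
        ds = rl.PatternDataset(
            data=np.vstack([row, row + diff] * 3),
            condition_ids=[0, 1] * 3,
            partition_ids=np.repeat([0, 1, 2], 2))
        rdm = rl.crossnobis(ds)
        assert rdm.values == pytest.approx([2.0])

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            ds = random_pattern_dataset(rng, n_cond=6, n_runs=3, n_voxels=10)
            got = rl.crossnobis(ds).values
            assert np.allclose(got, crossnobis_oracle(ds), atol=1e-10)

    def test_single_partition_rejected(self, rng):
        ds = random_pattern_dataset(rng, n_cond=3, n_runs=1)
        with pytest.raises(ValueError, match="2 partitions"):
            rl.crossnobis(ds)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_common_pattern_per_partition(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_pattern_dataset(rng, n_cond=4, n_runs=3, n_voxels=6)
        shifted = ds.data.copy()
        for p in ds.partitions:
            shifted[ds.partition_ids == p] += rng.standard_normal(6)
        ds2 = rl.PatternDataset(data=shifted, condition_ids=ds.condition_ids,
                                partition_ids=ds.partition_ids)
        assert np.allclose(rl.crossnobis(ds).values,
                           rl.crossnobis(ds2).values, atol=1e-10)

    def test_unbiased_under_null_while_naive_is_biased(self):
        # identical true patterns, noise only: crossnobis mean ~ 0,
        # non-crossvalidated distance strictly positive
        rng = np.random.default_rng(99)
        cross, naive = [], []
        for _ in range(300):
            ds = random_pattern_dataset(rng, n_cond=4, n_runs=4, n_voxels=20)
            cross.append(rl.crossnobis(ds).values.mean())
            naive.append(naive_distance(ds).values.mean())
        cross = np.array(cross)
        se = cross.std(ddof=1) / np.sqrt(len(cross))
        assert abs(cross.mean()) < 3 * se
        assert np.mean(naive) > 10 * se


class TestAverageAndBehavioralRDM:
    def test_group_sizes_for_6_plus_6(self, small_study):
        ds = small_study["datasets"][(0, 0)]
        rdm = rl.crossnobis(ds)
        out = rl.average_rdm(rdm)
        assert out["n_pairs"] == {"within_trained": 15, "within_untrained": 15,
                                  "between": 36, "overall": 66}

    def test_constant_rdm_all_means_equal(self):
        st_map = {0: "trained", 1: "trained", 2: "untrained", 3: "untrained"}
        rdm = rl.RDM(values=np.full(6, 3.5), conditions=[0, 1, 2, 3],
                     sequence_type=st_map)
        out = rl.average_rdm(rdm)
        for key in ("within_trained", "within_untrained", "overall"):
            assert out[key] == pytest.approx(3.5)

    def test_random_rdm_matches_hand_partition(self, rng):
        st_map = {c: ("trained" if c < 3 else "untrained") for c in range(6)}
        vals = rng.standard_normal(15)
        rdm = rl.RDM(values=vals, conditions=list(range(6)),
                     sequence_type=st_map)
        out = rl.average_rdm(rdm)
        by_group = {"tt": [], "uu": [], "between": []}
        for (a, b), v in zip(rdm.pairs, vals):
            key = ("tt" if a < 3 and b < 3 else
                   "uu" if a >= 3 and b >= 3 else "between")
            by_group[key].append(v)
        assert out["within_trained"] == pytest.approx(np.mean(by_group["tt"]))
        assert out["within_untrained"] == pytest.approx(np.mean(by_group["uu"]))

    def test_crossnobis_1d_closed_form_and_consistency(self, rng):
        # MTs {1, 2} in both of 2 runs, unit variance -> d = 1
        tab = pd.DataFrame({
            "condition": [0, 1, 0, 1], "partition": [0, 0, 1, 1],
            "value": [1.0, 2.0, 1.0, 2.0]})
        rdm = rl.crossnobis_1d(tab, residual_var=1.0)
        assert rdm.values == pytest.approx([1.0])
        # random table: must equal generic crossnobis with P = 1
        vals = rng.standard_normal(12)
        tab = pd.DataFrame({
            "condition": np.tile(np.arange(4), 3),
            "partition": np.repeat(np.arange(3), 4), "value": vals})
        got = rl.crossnobis_1d(tab, residual_var=1.0)
        ds = rl.PatternDataset(data=vals.reshape(-1, 1),
                               condition_ids=np.tile(np.arange(4), 3),
                               partition_ids=np.repeat(np.arange(3), 4))
        want = rl.crossnobis(ds, n_channels=1)
        assert np.allclose(got.values, want.values, atol=1e-12)


class TestCosineAndZNorm:
    def test_scale_invariance(self, rng):
        a = rng.standard_normal(20)
        assert rl.cosine_dissimilarity(a, 3.0 * a) == pytest.approx(0.0)

    def test_orthogonal_and_closed_form(self):
        assert rl.cosine_dissimilarity([1, 0], [0, 1]) == pytest.approx(1.0)
        assert rl.cosine_dissimilarity([1, 1], [1, 0]) == pytest.approx(
            1.0 - 1.0 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            rl.cosine_dissimilarity([0, 0], [1, 0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000),
           scale=st.floats(0.01, 100.0))
    def test_positive_scaling_invariance_property(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 10))
        d0 = rl.cosine_dissimilarity(a, b)
        assert rl.cosine_dissimilarity(scale * a, b) == pytest.approx(d0)

    def test_znormalize_invariances(self, rng):
        x = rng.standard_normal(50)
        z = rl.znormalize_map(x)
        assert abs(z.mean()) < 1e-12 and abs(z.std() - 1.0) < 1e-12
        assert np.allclose(rl.znormalize_map(x + 5.0), z)
        assert np.allclose(rl.znormalize_map(2.0 * x), z)
        with pytest.raises(ValueError):
            rl.znormalize_map(np.full(10, 3.0))


class TestMDS:
    def test_collinear_points_recovered_in_1d(self):
        # points 0, 1, 2 on a line; squared distances {1, 4, 1}
        D = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
        X = rl.classical_mds(D, k=1)
        d01 = abs(X[0, 0] - X[1, 0])
        d12 = abs(X[1, 0] - X[2, 0])
        d02 = abs(X[0, 0] - X[2, 0])
        assert np.allclose(sorted([d01, d12, d02]), [1, 1, 2], atol=1e-8)

    def test_euclidean_roundtrip(self, rng):
        pts = rng.standard_normal((5, 2))
        D = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        X = rl.classical_mds(D, k=2)
        D2 = ((X[:, None] - X[None]) ** 2).sum(-1)
        assert np.allclose(D, D2, atol=1e-8)

    def test_zero_rdm_collapses_to_origin(self):
        rdm = rl.RDM(values=np.zeros(3), conditions=[0, 1, 2])
        with pytest.warns(UserWarning):
            X = rl.classical_mds(rdm, k=1)
        assert np.allclose(X, 0.0)

    def test_matches_pcoa_reference(self, rng):
        from skbio.stats.ordination import pcoa

        pts = rng.standard_normal((6, 3))
        D = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        ours = rl.classical_mds(D, k=3)
        ref = pcoa(np.sqrt(D)).samples.to_numpy()[:, :3]
        aligned = procrustes_align(ours, ref)
        assert np.allclose(aligned, ref, atol=1e-6)


class TestSearchlight:
    def test_whole_region_neighborhood_equals_region_statistic(self, rng):
        ds = random_pattern_dataset(rng, n_cond=4, n_runs=3, n_voxels=12)
        nb = rl.Neighborhood(center_id="all", members=np.arange(12))
        stat = lambda d: rl.crossnobis(d).values.mean()
        out = rl.searchlight(ds, [nb], stat)
        assert out["all"] == pytest.approx(stat(ds))

    def test_duplicate_neighborhoods_identical_and_manual_loop(self, rng):
        ds = random_pattern_dataset(rng, n_cond=3, n_runs=3, n_voxels=10)
        nbs = [rl.Neighborhood(i, rng.choice(10, size=4, replace=False))
               for i in range(5)]
        nbs.append(rl.Neighborhood(99, nbs[0].members))
        stat = lambda d: float(d.data.sum())
        out = rl.searchlight(ds, nbs, stat)
        assert out[0] == out[99]
        for nb in nbs:
            assert out[nb.center_id] == pytest.approx(
                float(ds.data[:, nb.members].sum()))

    def test_invalid_voxels_rejected(self, rng):
        ds = random_pattern_dataset(rng, n_voxels=5)
        with pytest.raises(ValueError, match="invalid voxels"):
            rl.searchlight(ds, [rl.Neighborhood(0, [4, 7])], lambda d: 0.0)
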