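"""Pattern-component correlation models: likelihood, fitting, inference."""

import numpy as np
import pytest
from scipy import stats

import replearn as rl
from replearn.datasets import TRAINED
from replearn.pcm import (CorrelationModelFamily, CorrelationPCMResults,
                          _fold_selection, fit_model, loglik_at,
                          prepare_session_pair)


def mvn_oracle(Y, Z, G, noise):
    """Dense per-voxel multivariate-normal log-density."""
    N = Y.shape[0]
    V = Z @ G @ Z.T + np.diag(np.broadcast_to(noise, (N,)))
    return float(sum(stats.multivariate_normal.logpdf(y, mean=np.zeros(N),
                                                      cov=V,
                                                      allow_singular=False)
                     for y in Y.T))


def simulate_pair(rng, r, n_seq=6, n_runs=8, n_voxels=160, signal=1.0,
                  noise=8.0):
    """Two-session PatternDataset pair with known true correlation."""
    chol = np.linalg.cholesky(
        signal * np.array([[1.0, r], [r, 1.0]]) + 1e-12 * np.eye(2))
    out = []
    truths = np.einsum("ab,bcv->acv", chol,
                       rng.standard_normal((2, n_seq, n_voxels)))
    for m in range(2):
        data = truths[m][None] + np.sqrt(noise) * rng.standard_normal(
            (n_runs, n_seq, n_voxels))
        out.append(rl.PatternDataset(
            data=data.reshape(-1, n_voxels),
            condition_ids=np.tile(np.arange(n_seq), n_runs),
            partition_ids=np.repeat(np.arange(n_runs), n_seq)))
    return out[0], out[1]


class TestBuildG:
    def test_zero_correlation_identity(self):
        assert np.allclose(rl.build_G(0.0, 0.0, 0.0, 2), np.eye(4))

    def test_perfect_correlation_rank_k(self):
        G = rl.build_G(1.0, 0.0, 0.0, 3)
        assert np.allclose(G, np.block([[np.eye(3)] * 2] * 2))
        assert np.linalg.matrix_rank(G) == 3

    def test_off_diagonal_scaling(self):
        G = rl.build_G(0.5, np.log(4.0), 0.0, 2)
        assert np.allclose(G[:2, 2:], np.eye(2))  # 0.5 * sqrt(4 * 1)

    @pytest.mark.parametrize("r", [-1.0, -0.3, 0.0, 0.7, 1.0])
    def test_psd_for_any_parameters(self, r):
        G = rl.build_G(r, 1.3, -0.7, 4)
        assert np.linalg.eigvalsh(G).min() > -1e-10


class TestLoglik:
    def test_iid_normal_closed_form(self, rng):
        Y = rng.standard_normal((6, 4))
        Z = np.eye(6)
        L = rl.pcm_loglik(Y, Z, np.zeros((6, 6)), 1.0)
        expected = -0.5 * 24 * np.log(2 * np.pi) - 0.5 * (Y ** 2).sum()
        assert L == pytest.approx(expected)

    def test_matches_dense_mvn_oracle(self, rng):
        for _ in range(20):
            N = int(rng.integers(3, 12))
            K = int(rng.integers(1, 5))
            P = int(rng.integers(1, 8))
            Z = rng.standard_normal((N, K))
            A = rng.standard_normal((K, K))
            G = A @ A.T
            noise = rng.uniform(0.5, 2.0, size=N)
            Y = rng.standard_normal((N, P))
            got = rl.pcm_loglik(Y, Z, G, noise)
            want = mvn_oracle(Y, Z, G, noise)
            assert got == pytest.approx(want, rel=1e-8)

    def test_additive_over_voxels(self, rng):
        Y = rng.standard_normal((4, 3))
        Z = np.eye(4)
        G = np.diag([1.0, 2.0, 0.5, 1.5])
        one = rl.pcm_loglik(Y, Z, G, 1.0)
        two = rl.pcm_loglik(np.hstack([Y, Y]), Z, G, 1.0)
        assert two == pytest.approx(2 * one)

    def test_reduced_likelihood_equals_generic(self, rng):
        ds1, ds2 = simulate_pair(rng, 0.5, n_seq=4, n_runs=3, n_voxels=7)
        data = prepare_session_pair(ds1, ds2)
        for theta in (np.zeros(4), np.array([0.3, -0.2, 0.1, 0.4])):
            G = rl.build_G(0.5, theta[0], theta[1], data.q)
            noise = np.where(data.session_of_row == 0,
                             np.exp(theta[2]), np.exp(theta[3]))
            want = rl.pcm_loglik(data.Y, data.Z, G, noise)
            got = loglik_at(data, 0.5, theta)
            assert got == pytest.approx(want, rel=1e-10)


class TestFitting:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(77)
        signal, noise = 2.0, 4.0
        ds1, ds2 = simulate_pair(rng, 0.6, n_seq=6, n_runs=8,
                                 n_voxels=1000, signal=signal, noise=noise)
        data = prepare_session_pair(ds1, ds2)
        ll, theta, conv = fit_model(data, 0.6)
        assert conv
        assert np.exp(theta[0]) == pytest.approx(signal, rel=0.10)
        assert np.exp(theta[1]) == pytest.approx(signal, rel=0.10)
        assert np.exp(theta[2]) == pytest.approx(noise, rel=0.10)
        assert np.exp(theta[3]) == pytest.approx(noise, rel=0.10)

    def test_zero_signal_flat_curve(self):
        rng = np.random.default_rng(5)
        ds1, ds2 = simulate_pair(rng, 0.0, n_seq=6, n_runs=8, n_voxels=200,
                                 signal=0.0, noise=1.0)
        data = prepare_session_pair(ds1, ds2)
        lls = np.array([fit_model(data, r)[0]
                        for r in np.linspace(0, 1, 10)])
        assert lls.max() - lls.min() < 0.1

    def test_restart_from_optimum_is_stationary(self, rng):
        ds1, ds2 = simulate_pair(rng, 0.3, n_seq=4, n_runs=4, n_voxels=50)
        data = prepare_session_pair(ds1, ds2)
        ll, theta, _ = fit_model(data, 0.3)
        from replearn.pcm import _reduced_negloglik
        from scipy import optimize
        res = optimize.minimize(_reduced_negloglik, theta, args=(0.3, data),
                                jac=True, method="L-BFGS-B")
        assert -res.fun <= ll + 1e-6


class TestEvidenceCurves:
    def test_group_recovery_and_rowsum(self):
        rng = np.random.default_rng(31)
        pairs = [prepare_session_pair(*simulate_pair(rng, 0.6, n_voxels=300,
                                                     signal=1.0, noise=4.0))
                 for _ in range(8)]
        res = rl.evidence_curves(pairs)
        assert np.allclose(res.rel_loglik.sum(axis=1), 0.0, atol=1e-6)
        grid = res.family.r_grid
        assert abs(res.best_r - 0.6) <= (grid[1] - grid[0]) + 1e-9
        assert "winning correlation" in res.summary()

    def test_true_zero_correlation_hits_grid_bottom(self):
        rng = np.random.default_rng(13)
        pairs = [prepare_session_pair(*simulate_pair(rng, 0.0, n_voxels=300,
                                                     signal=1.0, noise=4.0))
                 for _ in range(8)]
        res = rl.evidence_curves(pairs)
        grid = res.family.r_grid
        assert res.best_r <= grid[1] + 1e-9


class TestCrossvalTest:
    def _fake_results(self, loglik):
        fam = CorrelationModelFamily(n_models=loglik.shape[1])
        return CorrelationPCMResults(
            family=fam, loglik=loglik,
            theta=np.zeros(loglik.shape + (4,)),
            converged=np.ones(loglik.shape, dtype=bool))

    def test_identical_results_give_zero_statistic(self, rng):
        ll = rng.standard_normal((6, 5))
        res = self._fake_results(ll)
        delta, t, p = rl.crossval_group_test(res, self._fake_results(ll.copy()))
        assert np.allclose(delta, 0.0) and t == 0.0 and p == 1.0

    def test_left_out_subject_never_influences_selection(self, rng):
        ll = rng.standard_normal((8, 6))
        for i in range(8):
            base = _fold_selection(ll, i)
            tampered = ll.copy()
            tampered[i] += rng.standard_normal(6) * 100
            assert _fold_selection(tampered, i) == base

    def test_argmax_ties_take_lower_grid_index(self):
        ll = np.zeros((4, 5))  # all ties
        assert _fold_selection(ll, 0) == 0

    def test_detects_true_correlation_difference(self):
        rng = np.random.default_rng(101)
        pairs_a = [prepare_session_pair(*simulate_pair(
            rng, 0.3, n_voxels=300, signal=2.0, noise=4.0)) for _ in range(10)]
        pairs_b = [prepare_session_pair(*simulate_pair(
            rng, 0.8, n_voxels=300, signal=2.0, noise=4.0)) for _ in range(10)]
        res_a = rl.evidence_curves(pairs_a)
        res_b = rl.evidence_curves(pairs_b)
        delta, t, p = rl.crossval_group_test(res_a, res_b)
        assert p < 0.05 and t < 0


class TestWinningModelMap:
    def _results_with_curve(self, curve, n_subj=5):
        curve = np.asarray(curve, dtype=float)
        fam = CorrelationModelFamily(n_models=len(curve))
        ll = np.tile(curve, (n_subj, 1)) + np.linspace(0, 1, n_subj)[:, None]
        return CorrelationPCMResults(
            family=fam, loglik=ll, theta=np.zeros(ll.shape + (4,)),
            converged=np.ones(ll.shape, dtype=bool))

    def test_flat_curves_fully_masked(self):
        res = {loc: self._results_with_curve(np.zeros(5)) for loc in "ab"}
        out = rl.winning_model_map(res, evidence_threshold=1.0)
        assert all(np.isnan(v) for v in out.values())

    def test_strong_location_survives(self):
        strong = self._results_with_curve([0, 0, 5, 0, 0])
        weak = self._results_with_curve([0, 0, 0.5, 0, 0])
        out = rl.winning_model_map({"s": strong, "w": weak})
        assert out["s"] == pytest.approx(strong.family.r_grid[2])
        assert np.isnan(out["w"])

    def test_threshold_zero_keeps_every_argmax(self):
        res = {0: self._results_with_curve([0, 0.2, 0, 0, 0])}
        out = rl.winning_model_map(res, evidence_threshold=0.0)
        assert not np.isnan(out[0])
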