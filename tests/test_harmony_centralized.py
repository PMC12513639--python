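"""Centralized (pooled) Harmony: objective, updates, correction, full runs."""

import numpy as np
import pytest

import fedharmony as fh
from fedharmony import _kernels as kern
from fedharmony import centralized
from fedharmony.centralized import (
    HarmonyState,
    compute_W,
    correct,
    objective,
    run_harmony,
    update_R,
)
from fedharmony.config import Hyperparameters

from conftest import random_harmony_state


def brute_objective(state, sigma, theta):
    """Scalar-by-scalar summation oracle for the clustering objective."""
    K, N = state.R.shape
    total = 0.0
    for i in range(N):
        b = int(np.argmax(state.phi[:, i]))
        for k in range(K):
            r = state.R[k, i]
            dist = float(np.sum((state.Z_cos[:, i] - state.Y[:, k]) ** 2))
            total += r * dist
            if r > 0:
                total += sigma * r * np.log(r)
            total += sigma * theta * r * np.log(
                (state.O[k, b] + 1) / (state.E[k, b] + 1)
            )
    return total


class TestObjective:
    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(0)
        state = random_harmony_state(rng, d=3, N=7, K=2, B=2)
        hp = Hyperparameters(sigma=0.2, theta=1.5)
        assert objective(state, hp) == pytest.approx(
            brute_objective(state, 0.2, 1.5), abs=1e-10
        )

    def test_kmeans_limit_with_hard_assignments(self):
        """sigma=theta=0 with one-hot R gives the k-means within-cluster cost."""
        rng = np.random.default_rng(1)
        state = random_harmony_state(rng, d=3, N=10, K=3, B=2)
        dist = kern.cosine_sq_dist(state.Y, state.Z_cos)
        nearest = np.argmin(dist, axis=0)
        state.R = np.zeros_like(state.R)
        state.R[nearest, np.arange(10)] = 1.0
        state.O = state.R @ state.phi.T
        state.E = np.outer(state.O.sum(axis=1), state.Pr_b)
        hp = Hyperparameters(sigma=0.0, theta=0.0)
        expected = float(dist[nearest, np.arange(10)].sum())
        assert objective(state, hp) == pytest.approx(expected, abs=1e-12)
        # entropy term is exactly 0 for one-hot R (0*log 0 convention)
        hp_entropy = Hyperparameters(sigma=5.0, theta=0.0)
        assert objective(state, hp_entropy) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_state_rejected(self):
        rng = np.random.default_rng(2)
        state = random_harmony_state(rng)
        state.Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="nonfinite"):
            objective(state, Hyperparameters())


class TestUpdateR:
    def test_single_cluster_normalizes_to_ones(self):
        rng = np.random.default_rng(3)
        state = random_harmony_state(rng, K=1)
        update_R(state, Hyperparameters(), np.arange(state.R.shape[1]))
        np.testing.assert_allclose(state.R, 1.0)

    def test_equidistant_centroids_split_evenly(self):
        """theta=0: a cell equidistant from two centroids gets (1/2, 1/2)."""
        Z = np.array([[1.0], [0.0]])
        Y = kern.l2_normalize_columns(np.array([[1.0, 1.0], [1.0, -1.0]]))
        phi = np.ones((1, 1))
        R = np.array([[0.3], [0.7]])
        state = HarmonyState(Z, Z.copy(), phi, R, Y, R @ phi.T,
                             R @ phi.T, np.array([1.0]))
        update_R(state, Hyperparameters(theta=0.0), np.array([0]))
        np.testing.assert_allclose(state.R[:, 0], [0.5, 0.5], atol=1e-12)

    def test_logistic_value_for_aligned_and_orthogonal_centroids(self):
        """Y1.Z=1, Y2.Z=0, sigma=0.1, theta=0 -> R = (1, e^-20)/(1+e^-20)."""
        Z = np.array([[1.0], [0.0]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        phi = np.ones((1, 1))
        R = np.full((2, 1), 0.5)
        state = HarmonyState(Z, Z.copy(), phi, R, Y, R @ phi.T,
                             R @ phi.T, np.array([1.0]))
        update_R(state, Hyperparameters(sigma=0.1, theta=0.0), np.array([0]))
        expected = np.array([1.0, np.exp(-20.0)]) / (1.0 + np.exp(-20.0))
        np.testing.assert_allclose(state.R[:, 0], expected, rtol=1e-12)

    def test_sigma_zero_rejected(self):
        rng = np.random.default_rng(4)
        state = random_harmony_state(rng)
        with pytest.raises(ValueError, match="sigma"):
            update_R(state, Hyperparameters(sigma=0.0), np.array([0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bookkeeping_invariants_preserved(self, seed):
        """Columns of R sum to 1; O = R phi^T; E row-sums track O row-sums."""
        rng = np.random.default_rng(seed)
        state = random_harmony_state(rng, d=4, N=30, K=5, B=3)
        hp = Hyperparameters(sigma=0.15, theta=2.0)
        for block in kern.random_blocks(30, 0.2, rng):
            update_R(state, hp, block)
            np.testing.assert_allclose(state.R.sum(axis=0), 1.0, atol=1e-10)
            np.testing.assert_allclose(state.O, state.R @ state.phi.T, atol=1e-8)
            np.testing.assert_allclose(
                state.E.sum(axis=1), state.O.sum(axis=1), atol=1e-8
            )

    def test_first_block_pass_decreases_objective(self, small_embeddings):
        """From a fresh initialization one full block pass strictly descends."""
        Z = np.concatenate(small_embeddings, axis=1)
        phi = np.repeat(np.eye(3), [z.shape[1] for z in small_embeddings], axis=1)
        hp = Hyperparameters(seed=2, n_clusters=10)
        state = centralized.initialize_state(Z, phi, hp)
        rng = np.random.default_rng(0)
        before = objective(state, hp)
        for block in kern.random_blocks(Z.shape[1], hp.block_fraction, rng):
            update_R(state, hp, block)
        assert objective(state, hp) < before


class TestComputeW:
    def test_zero_assignments_give_zero_factor(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(3, 8))
        phi = np.zeros((2, 8))
        phi[0, :4] = 1.0
        phi[1, 4:] = 1.0
        W = compute_W(Z, np.zeros(8), phi, lamb=1.0)
        np.testing.assert_array_equal(W, 0.0)

    def test_ridge_shrinkage_monotone(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(3, 20))
        phi = np.zeros((2, 20))
        phi[0, :10] = 1.0
        phi[1, 10:] = 1.0
        R_k = rng.random(20)
        Ws = [np.abs(compute_W(Z, R_k, phi, lamb)) for lamb in (1.0, 1e3, 1e6)]
        assert np.all(Ws[1] <= Ws[0] + 1e-12)
        assert np.all(Ws[2] <= Ws[1] + 1e-12)

    def test_two_cell_two_batch_hand_solve(self):
        """d=1, R_k=(1,1), lamb=1: explicit 3x3 system built by hand."""
        z1, z2 = 1.7, -0.4
        Z = np.array([[z1, z2]])
        phi = np.array([[1.0, 0.0], [0.0, 1.0]])
        S = np.array([[2.0, 1.0, 1.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        T = np.array([[z1 + z2], [z1], [z2]])
        Lam = np.diag([0.0, 1.0, 1.0])
        expected = np.linalg.solve(S + Lam, T)
        expected[0, :] = 0.0
        W = compute_W(Z, np.ones(2), phi, lamb=1.0)
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_small_ridge_recovers_batch_mean_centering(self):
        """K=1, R=1, lamb->0: corrected batch means coincide."""
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(3, 30)) + 2.0
        phi = np.zeros((2, 30))
        phi[0, :12] = 1.0
        phi[1, 12:] = 1.0
        R = np.ones((1, 30))
        W = compute_W(Z, R[0], phi, lamb=1e-9)
        Z_hat = correct(Z, R, phi, [W])
        m0 = Z_hat[:, :12].mean(axis=1)
        m1 = Z_hat[:, 12:].mean(axis=1)
        np.testing.assert_allclose(m0, m1, atol=1e-6)
        # per-batch centering up to the common post-correction offset
        centered = Z.copy()
        centered[:, :12] -= Z[:, :12].mean(axis=1, keepdims=True)
        centered[:, 12:] -= Z[:, 12:].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(Z_hat - m0[:, None], centered, atol=1e-6)

    def test_singular_system_without_ridge_raises(self):
        Z = np.array([[1.0, 2.0]])
        phi = np.array([[1.0, 1.0], [0.0, 0.0]])  # batch 1 empty
        with pytest.raises(np.linalg.LinAlgError, match="lamb"):
            compute_W(Z, np.ones(2), phi, lamb=0.0)


class TestCorrect:
    def test_zero_factors_identity(self):
        rng = np.random.default_rng(9)
        state = random_harmony_state(rng, d=2, N=6, K=2, B=2)
        W = [np.zeros((3, 2)) for _ in range(2)]
        np.testing.assert_array_equal(correct(state.Z_orig, state.R, state.phi, W),
                                      state.Z_orig)

    def test_matches_per_cell_loop(self):
        rng = np.random.default_rng(10)
        state = random_harmony_state(rng, d=2, N=3, K=2, B=2)
        W = [rng.normal(size=(3, 2)) for _ in range(2)]
        for W_k in W:
            W_k[0, :] = 0.0
        Z_hat = correct(state.Z_orig, state.R, state.phi, W)
        phi_star = np.vstack([np.ones(3), state.phi])
        for i in range(3):
            expected = state.Z_orig[:, i] - sum(
                state.R[k, i] * (W[k].T @ phi_star[:, i]) for k in range(2)
            )
            np.testing.assert_allclose(Z_hat[:, i], expected, atol=1e-12)

    def test_single_cluster_subtracts_one_vector_per_batch(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(3, 8))
        phi = np.ones((1, 8))
        R = np.ones((1, 8))
        W = [np.vstack([np.zeros(3), rng.normal(size=3)])]
        Z_hat = correct(Z, R, phi, W)
        shifts = Z - Z_hat
        np.testing.assert_allclose(shifts - shifts[:, [0]], 0.0, atol=1e-12)

    def test_nonzero_intercept_rejected(self):
        rng = np.random.default_rng(12)
        state = random_harmony_state(rng, d=2, N=4, K=1, B=2)
        W = [rng.normal(size=(3, 2))]
        with pytest.raises(ValueError, match="intercept"):
            correct(state.Z_orig, state.R, state.phi, W)


class TestRunHarmony:
    def test_objective_descent_within_clustering_phases(self, small_embeddings):
        Z = np.concatenate(small_embeddings, axis=1)
        phi = np.repeat(np.eye(3), [z.shape[1] for z in small_embeddings], axis=1)
        hp = Hyperparameters(seed=2, n_clusters=10)
        res = run_harmony(Z, phi, hp)
        for trace in res.objective_trace:
            diffs = np.diff(trace)
            assert np.all(diffs <= 1e-6 * np.abs(trace[:-1]))

    def test_less_correction_needed_without_batch_shift(self):
        def corr_norm(shift):
            cfg = fh.ScenarioConfig(
                n_sites=2, cells_per_site=(100, 100), n_celltypes=3,
                n_features=25, batch_shift_scale=shift, noise_sd=1.0, seed=5,
            )
            ds = fh.generate_scenario(cfg)
            _, Z_sites = fh.federated_pca(ds.matrices, d=8)
            Z = np.concatenate(Z_sites, axis=1)
            phi = np.repeat(np.eye(2), [100, 100], axis=1)
            res = run_harmony(Z, phi, Hyperparameters(seed=2, n_clusters=8))
            return np.linalg.norm(Z - res.Z_corr)

        assert corr_norm(0.0) < corr_norm(5.0)

    def test_single_batch_is_left_unchanged_by_default_ridge(self):
        """With the intercept unpenalized, one batch means no correction."""
        rng = np.random.default_rng(13)
        Z = rng.normal(size=(4, 60))
        phi = np.ones((1, 60))
        res = run_harmony(Z, phi, Hyperparameters(seed=3, n_clusters=4))
        np.testing.assert_allclose(res.Z_corr, Z, atol=1e-10)

    def test_single_batch_literal_ridge_absorbs_cluster_offsets(self):
        """ridge_intercept=True penalizes the intercept, so the batch row is nonzero."""
        rng = np.random.default_rng(14)
        Z = rng.normal(size=(4, 60)) + 3.0
        phi = np.ones((1, 60))
        res = run_harmony(
            Z, phi, Hyperparameters(seed=3, n_clusters=4, ridge_intercept=True)
        )
        assert np.linalg.norm(Z - res.Z_corr) > 1.0
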