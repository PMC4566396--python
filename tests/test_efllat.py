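"""Dictionary-learning model: penalties, proxes, block updates, selection."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear

from oncodict import simulate
from oncodict.efllat import (Hyperparams, fit, make_weights, objective,
                             prox_sq_l1, prox_weighted_tv, select_hyperparams,
                             select_n_atoms, update_atoms, update_coefficients,
                             weighted_tv)


class TestWeightedTV:
    @pytest.mark.parametrize("beta, w, expected", [
        ([0.5, 0.5, 0.5], [1, 1], 0.0),        # constant signal
        ([0, 1, 0], [1, 0], 1.0),              # 1*|1| + 0*|-1|
        ([0, 1, 1, 0], [1, 1, 1], 2.0),
    ])
    def test_direct_summation(self, beta, w, expected):
        assert weighted_tv(np.array(beta, float), np.array(w, float)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_tv(np.zeros(4), np.zeros(4))


class TestMakeWeights:
    def test_flat_is_one_except_boundaries(self, toy_grid):
        w = make_weights(toy_grid, "flat")
        assert w.shape == (toy_grid.L - 1,)
        assert np.all(w[toy_grid.boundary] == 0)
        assert np.all(w[~toy_grid.boundary] == 1)

    def test_gap_equal_gaps_give_exp_minus_one(self, toy_grid):
        # toy grid probes are equally spaced within and between bands of an arm
        w = make_weights(toy_grid, "gap")
        interior = w[~toy_grid.boundary]
        assert np.allclose(interior, np.exp(-1.0))
        assert np.all(w[toy_grid.boundary] == 0)

    def test_unknown_schema(self, toy_grid):
        with pytest.raises(ValueError, match="schema"):
            make_weights(toy_grid, "banana")


class TestProxSqL1:
    def test_sigma_zero_is_identity(self, rng):
        z = rng.normal(size=7)
        assert np.array_equal(prox_sq_l1(z, 0.0), z)

    def test_large_sigma_shrinks_to_zero(self):
        out = prox_sq_l1(np.array([1.0, 0.0]), 100.0)
        assert np.all(np.abs(out) < 0.01) and out[1] == 0

    @pytest.mark.parametrize("sigma", [0.1, 1.0])
    def test_matches_threshold_scan_oracle(self, sigma, rng):
        """The minimizer is a soft-threshold of z; an exhaustive scan over
        a dense grid of thresholds bounds the optimum independently."""
        for _ in range(20):
            z = rng.normal(size=rng.integers(2, 6))
            out = prox_sq_l1(z, sigma)
            obj = lambda x: 0.5 * np.sum((x - z) ** 2) + sigma * np.sum(np.abs(x)) ** 2
            best = min(
                obj(np.sign(z) * np.maximum(np.abs(z) - t, 0))
                for t in np.linspace(0, np.abs(z).max(), 4001)
            )
            assert obj(out) <= best + 1e-3


class TestProxWeightedTV:
    def test_sigma_zero_is_identity(self, rng):
        z = rng.normal(size=6)
        assert np.array_equal(prox_weighted_tv(z, np.ones(5), 0.0), z)

    def test_piecewise_constant_is_fixed_point(self):
        z = np.array([1.0, 1.0, 1.0, -2.0, -2.0])
        w = np.array([1.0, 1.0, 0.0, 1.0])  # zero weight at the step
        for sigma in (0.1, 10.0):
            assert np.allclose(prox_weighted_tv(z, w, sigma), z)

    @pytest.mark.parametrize("sigma", [0.05, 0.3, 1.5])
    def test_matches_box_qp_dual_oracle(self, sigma, rng):
        """The TV prox dual is a box-constrained least-squares problem
        solved independently by scipy's lsq_linear: x = z - D^T u*."""
        for _ in range(10):
            n = int(rng.integers(3, 6))
            z = rng.normal(size=n)
            w = rng.uniform(0.3, 1.5, size=n - 1)
            out = prox_weighted_tv(z, w, sigma)
            D = np.diff(np.eye(n), axis=0)          # (n-1, n)
            res = lsq_linear(D.T, z, bounds=(-sigma * w, sigma * w), tol=1e-14)
            oracle = z - D.T @ res.x
            assert np.allclose(out, oracle, atol=1e-4)

    def test_zero_weights_decouple_segments(self, rng):
        z = rng.normal(size=10)
        w = np.ones(9)
        w[4] = 0.0
        joint = prox_weighted_tv(z, w, 0.7)
        left = prox_weighted_tv(z[:5], w[:4], 0.7)
        right = prox_weighted_tv(z[5:], w[5:], 0.7)
        assert np.allclose(joint, np.concatenate([left, right]))


class TestObjective:
    def test_all_zero_vanishes(self):
        h = Hyperparams(lambda_=1, mu=1, tau=1, J=1)
        Y = np.zeros((2, 3))
        assert objective(Y, np.zeros((3, 1)), np.zeros((1, 2)), np.ones(2), h) == 0

    def test_exact_reconstruction_no_penalty(self):
        h = Hyperparams(J=1)
        Y = np.array([[1.0, 1.0]])
        B = np.array([[1.0], [1.0]])
        Th = np.array([[1.0]])
        assert objective(Y, B, Th, np.ones(1), h) == pytest.approx(0.0)

    def test_squared_l1_atom_penalty(self):
        h = Hyperparams(lambda_=1.0, J=1)
        Y = np.array([[1.0, 1.0]])
        B = np.array([[1.0], [1.0]])
        Th = np.array([[1.0]])
        # ||beta||_1^2 = (1 + 1)^2 = 4
        assert objective(Y, B, Th, np.ones(1), h) == pytest.approx(4.0)

    def test_theta_outside_box_is_an_error(self):
        h = Hyperparams(J=1, theta_max=1.0)
        with pytest.raises(ValueError, match="box"):
            objective(np.zeros((1, 2)), np.zeros((2, 1)), np.array([[1.5]]),
                      np.ones(1), h)


class TestBlockUpdates:
    def test_coefficients_reach_least_squares_with_orthonormal_atoms(self, rng):
        L, J, S = 8, 3, 4
        B, _ = np.linalg.qr(rng.normal(size=(L, J)))
        # choose Y so that B^T y is within [0, theta_max]
        Theta_true = rng.uniform(0.1, 0.9, size=(J, S))
        Y = (B @ Theta_true).T
        h = Hyperparams(tau=0.0, theta_max=10.0, J=J)
        Th = rng.uniform(0, 0.5, size=(J, S))
        for _ in range(200):
            Th = update_coefficients(Y, B, Th, h)
        assert np.allclose(Th, B.T @ Y.T, atol=1e-6)

    def test_exact_single_atom_representation(self):
        beta = np.array([1.0, 0.0, 2.0])
        B = np.column_stack([beta, np.array([0.0, 1.0, 0.0])])
        Y = (0.5 * beta)[None, :]
        h = Hyperparams(tau=0.0, theta_max=1.0, J=2)
        Th = np.full((2, 1), 0.25)
        for _ in range(300):
            Th = update_coefficients(Y, B, Th, h)
        assert np.allclose(Th[:, 0], [0.5, 0.0], atol=1e-6)

    def test_large_tau_drives_theta_to_zero(self, rng):
        B = rng.normal(size=(6, 2))
        Y = rng.normal(size=(3, 6))
        h = Hyperparams(tau=1e6, J=2)
        Th = rng.uniform(0, 1, size=(2, 3))
        for _ in range(100):
            Th = update_coefficients(Y, B, Th, h)
        assert np.all(Th < 1e-5)

    def test_atoms_converge_to_samples_when_unpenalized(self, rng):
        L, S = 6, 3
        Y = rng.normal(size=(S, L))
        h = Hyperparams(lambda_=0.0, mu=0.0, J=S)
        Theta = np.eye(S)
        B = rng.normal(size=(L, S)) * 0.1
        w = np.ones(L - 1)
        for _ in range(300):
            B = update_atoms(Y, Theta, B, h, w)
        assert np.allclose(B, Y.T, atol=1e-5)

    def test_huge_mu_flattens_atoms_within_segments(self, rng):
        L, S = 10, 4
        Y = rng.normal(size=(S, L))
        w = np.ones(L - 1)
        w[4] = 0.0  # two segments
        h = Hyperparams(mu=1e5, J=1)
        Theta = rng.uniform(0.2, 1.0, size=(1, S))
        B = rng.normal(size=(L, 1))
        for _ in range(100):
            B = update_atoms(Y, Theta, B, h, w)
        assert np.ptp(B[:5, 0]) < 1e-6
        assert np.ptp(B[5:, 0]) < 1e-6


class TestFit:
    def test_zero_data_reaches_zero_objective(self, rng):
        Y = np.zeros((4, 12))
        h = Hyperparams(J=2, seed=0, max_iter=500)
        res = fit(Y, h, np.ones(11))
        assert res.objective < 1e-8

    def test_noiseless_planted_composite_is_reconstructed(self, toy_grid):
        B_star = simulate.generate_atoms(toy_grid, 2, seed=7)
        cohort, _ = simulate.generate_cohort(B_star, 20, toy_grid,
                                             noise_sd=0.0, seed=7)
        w = make_weights(toy_grid)
        h = Hyperparams(lambda_=1e-4, mu=1e-3, tau=1e-4, J=2, seed=1, max_iter=400)
        res = fit(cohort, h, w)
        rel = (np.linalg.norm(cohort.Y.T - res.B @ res.Theta) /
               np.linalg.norm(cohort.Y)) ** 2
        assert rel < 0.01

    def test_identical_seeds_give_identical_traces(self, toy_grid):
        B_star = simulate.generate_atoms(toy_grid, 2, seed=3)
        cohort, _ = simulate.generate_cohort(B_star, 10, toy_grid, seed=3)
        w = make_weights(toy_grid)
        h = Hyperparams(lambda_=0.01, mu=0.5, tau=0.01, J=2, seed=42, max_iter=50)
        r1, r2 = fit(cohort, h, w), fit(cohort, h, w)
        assert r1.objective_trace == r2.objective_trace
        assert np.array_equal(r1.B, r2.B)

    def test_trace_is_monotone_and_theta_in_box(self, toy_grid):
        B_star = simulate.generate_atoms(toy_grid, 3, seed=5)
        cohort, _ = simulate.generate_cohort(B_star, 15, toy_grid, seed=5)
        w = make_weights(toy_grid)
        for seed in (0, 1):
            h = Hyperparams(lambda_=0.05, mu=2.0, tau=0.05, J=3, seed=seed,
                            max_iter=60)
            res = fit(cohort, h, w)
            tr = np.array(res.objective_trace)
            assert np.all(np.diff(tr) <= 1e-9 * (1 + np.abs(tr[:-1])))
            assert res.Theta.min() >= 0 and res.Theta.max() <= h.theta_max + 1e-12


class TestSelectNAtoms:
    def test_exact_rank_identity(self, rng):
        U = rng.normal(size=(20, 2))
        V = rng.normal(size=(2, 50))
        Y = U @ V
        assert select_n_atoms(Y, fraction=0.9) == 2

    def test_equal_components_follow_symmetry(self):
        # 5 orthonormal directions, each appearing as +v and -v: column
        # means are zero and all 5 components carry equal variance
        L = 25
        V = np.eye(L)[:5]
        Y = np.vstack([V, -V])
        assert select_n_atoms(Y, fraction=0.5) == 3   # ceil(0.5 * 5)
        assert select_n_atoms(Y, fraction=1.0) == 5

    def test_matches_eigendecomposition_oracle(self, toy_grid):
        B_star = simulate.generate_atoms(toy_grid, 3, seed=11)
        cohort, _ = simulate.generate_cohort(B_star, 40, toy_grid, seed=11)
        Yc = cohort.Y - cohort.Y.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Yc @ Yc.T))[::-1]
        ratio = np.cumsum(evals) / evals.sum()
        expected = int(np.searchsorted(ratio, 0.70 - 1e-12) + 1)
        assert select_n_atoms(cohort, fraction=0.70) == expected

    def test_zero_variance_returns_one(self):
        assert select_n_atoms(np.ones((5, 8))) == 1


class TestSelectHyperparams:
    def test_single_triple_grid_returns_it(self, toy_grid):
        B_star = simulate.generate_atoms(toy_grid, 2, seed=2)
        cohort, _ = simulate.generate_cohort(B_star, 8, toy_grid, seed=2)
        w = make_weights(toy_grid)
        h = Hyperparams(J=2, seed=0, max_iter=40)
        best, table, _ = select_hyperparams(cohort, [(0.01, 0.5, 0.01)], h, w)
        assert best == (0.01, 0.5, 0.01)
        assert len(table) == 1

    def test_argmin_is_self_consistent_with_table(self, toy_grid):
        B_star = simulate.generate_atoms(toy_grid, 2, seed=4)
        cohort, _ = simulate.generate_cohort(B_star, 10, toy_grid, seed=4)
        w = make_weights(toy_grid)
        h = Hyperparams(J=2, seed=0, max_iter=40)
        grid = [(l, m, t) for l in (1e-3, 1e-2) for m, t in ((0.1, 1e-3), (1.0, 1e-2))]
        best, table, fitres = select_hyperparams(cohort, grid, h, w)
        assert table.loc[table["bic"].idxmin(), "bic"] == pytest.approx(
            table.set_index(["lambda", "mu", "tau"]).loc[best, "bic"])
        assert fitres.B.shape == (toy_grid.L, 2)

    def test_empty_grid_rejected(self, toy_grid, rng):
        with pytest.raises(ValueError):
            select_hyperparams(rng.normal(size=(3, 5)), [], Hyperparams(J=1), np.ones(4))
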