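import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bregtomo import (DivergenceError, SolverConfig, default_parameters,
                      l1sb_solve, l2cg_solve, lbsr_solve, objective_value,
                      shrink)
from bregtomo.solvers import estimate_sigma_max


class TestShrink:
    @pytest.mark.parametrize("x,gamma,expect", [
        (5.0, 2.0, 3.0),
        (-5.0, 2.0, -3.0),
        (1.0, 2.0, 0.0),
        (0.0, 2.0, 0.0),
    ])
    def test_closed_form_cases(self, x, gamma, expect):
        assert shrink(x, gamma) == expect

    @given(st.floats(-100, 100), st.floats(0, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_soft_threshold_properties(self, x, gamma):
        y = float(shrink(x, gamma))
        assert abs(y) <= abs(x)                 # non-expansive toward 0
        assert y * x >= 0                       # never flips sign
        if abs(x) <= gamma:
            assert y == 0.0

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            shrink(1.0, -0.1)


class TestObjective:
    def test_zero_solution(self):
        A = np.eye(3)
        phi = np.array([1.0, 2.0, 2.0])
        assert objective_value(A, phi, np.zeros(3), 1.0) == 0.5 * 9.0

    def test_direct_evaluation(self):
        A = np.eye(2)
        assert objective_value(A, np.zeros(2), np.array([1.0, -1.0]),
                               2.0) == 5.0

    def test_mu_zero_is_half_residual(self, rng):
        A = rng.normal(size=(4, 6))
        phi = rng.normal(size=4)
        S = rng.normal(size=6)
        r = A @ S - phi
        assert np.isclose(objective_value(A, phi, S, 0.0), 0.5 * r @ r)


class TestDefaultParameters:
    def test_scalar_operator_step_size(self):
        cfg = default_parameters(np.array([[2.0]]), np.array([2.0]))
        assert np.isclose(cfg.delta, 0.25)

    def test_orthonormal_rows_unit_step(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        A = q[:4]
        cfg = default_parameters(A, rng.normal(size=4))
        assert np.isclose(cfg.delta, 1.0, rtol=1e-6)

    def test_degenerate_data_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cfg = default_parameters(np.eye(3), np.zeros(3))
        assert cfg.mu > 0

    def test_zero_operator_raises(self):
        with pytest.raises(ValueError):
            default_parameters(np.zeros((2, 2)), np.ones(2))

    def test_l1sb_rule_is_one_percent_of_lambda_max(self, rng):
        A = rng.normal(size=(5, 9))
        phi = rng.normal(size=5)
        cfg = default_parameters(A, phi, solver="l1sb")
        assert np.isclose(cfg.mu, 0.01 * np.abs(A.T @ phi).max())


class TestLinearizedBregman:
    def test_zero_data_returns_zero_immediately(self):
        r = lbsr_solve(np.array([[2.0]]), np.array([0.0]),
                       SolverConfig(mu=1.0, delta=0.25))
        assert r.S == 0.0 and r.iterations == 1 and r.converged

    def test_hand_iterated_scalar_example(self):
        # A = [2], Phi = [2], mu = 1, delta = 0.25:
        # v1 = 4, S1 = 0.75; v2 = 5, S2 = 1.0; v3 = 5, S3 = 1.0 -> stop
        r = lbsr_solve(np.array([[2.0]]), np.array([2.0]),
                       SolverConfig(mu=1.0, delta=0.25))
        assert r.iterations == 3 and r.converged
        assert np.isclose(r.S[0], 1.0)
        assert np.isclose(r.v_final[0], 5.0)

    def test_sparse_recovery_small_instance(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(20, 50)) / np.sqrt(20)
        support = rng.choice(50, 3, replace=False)
        s_true = np.zeros(50)
        s_true[support] = rng.uniform(0.5, 1.5, 3)
        phi = A @ s_true
        delta = 1.0 / estimate_sigma_max(A) ** 2
        cfg = SolverConfig(mu=5 * s_true.max() / delta, delta=delta,
                           epsilon=1e-6, max_iter=20000)
        r = lbsr_solve(A, phi, cfg)
        rec = np.nonzero(np.abs(r.S) > 1e-3 * np.abs(r.S).max())[0]
        assert set(rec) == set(support)
        assert np.linalg.norm(r.S - s_true) / np.linalg.norm(s_true) <= 1e-2

    def test_iterate_satisfies_shrinkage_identity(self, rng):
        A = rng.normal(size=(6, 10))
        phi = rng.normal(size=6)
        cfg = default_parameters(A, phi)
        r = lbsr_solve(A, phi, cfg)
        assert np.allclose(r.S, cfg.delta * shrink(r.v_final, cfg.mu),
                           atol=1e-14)

    def test_final_iterate_is_prox_minimizer(self):
        # S = delta*shrink(v, mu) minimizes
        # mu*|s| + (s - delta*v)^2/(2*delta) in every coordinate;
        # check against a dense grid search on random instances
        rng = np.random.default_rng(42)
        for _ in range(50):
            m, n = rng.integers(3, 8), rng.integers(3, 8)
            A = rng.normal(size=(m, n))
            phi = rng.normal(size=m)
            cfg = default_parameters(A, phi, max_iter=50)
            r = lbsr_solve(A, phi, cfg)
            for i in rng.choice(n, size=min(3, n), replace=False):
                v = r.v_final[i]
                dv = cfg.delta * v
                grid = np.linspace(min(0.0, dv) - 0.5,
                                   max(0.0, dv) + 0.5, 8001)
                costs = (cfg.mu * np.abs(grid)
                         + (grid - cfg.delta * v) ** 2 / (2 * cfg.delta))
                best = grid[np.argmin(costs)]
                assert abs(r.S[i] - best) < 1e-3

    def test_consistent_system_residual_vanishes(self, rng):
        A = rng.normal(size=(8, 20))
        s_true = np.zeros(20)
        s_true[[3, 11]] = [1.0, -0.5]
        phi = A @ s_true
        delta = 1.0 / estimate_sigma_max(A) ** 2
        cfg = SolverConfig(mu=1.0, delta=delta, epsilon=1e-12,
                           max_iter=50000)
        r = lbsr_solve(A, phi, cfg)
        assert r.residual_history[-1] <= 1e-6 * np.linalg.norm(phi)

    def test_stops_at_first_tolerance_crossing(self, rng):
        A = rng.normal(size=(10, 15))
        phi = rng.normal(size=10)
        cfg = default_parameters(A, phi)
        r = lbsr_solve(A, phi, cfg)
        if r.converged:
            hist = r.rel_change_history
            started = np.isfinite(hist)
            inside = hist[started][:-1]
            assert np.all(inside > cfg.epsilon)
            assert hist[-1] <= cfg.epsilon

    def test_divergent_step_size_aborts(self, rng):
        A = rng.normal(size=(10, 10)) + 5 * np.eye(10)
        phi = rng.normal(size=10)
        with pytest.raises(DivergenceError, match="delta"):
            lbsr_solve(A, phi, SolverConfig(mu=1e-6, delta=100.0,
                                            max_iter=500))

    def test_nonneg_projection(self, rng):
        A = rng.normal(size=(10, 15))
        phi = rng.normal(size=10)
        cfg = default_parameters(A, phi)
        cfg.nonneg = True
        r = lbsr_solve(A, phi, cfg)
        assert np.all(r.S >= 0)


class TestTikhonovCG:
    def test_identity_no_regularization(self):
        phi = np.array([1.0, -2.0, 3.0])
        r = l2cg_solve(np.eye(3), phi, lam=0.0)
        assert np.allclose(r.S, phi, atol=1e-10)

    def test_identity_unit_regularization(self):
        phi = np.array([1.0, -2.0, 3.0])
        r = l2cg_solve(np.eye(3), phi, lam=1.0)
        assert np.allclose(r.S, phi / 2.0, atol=1e-10)

    def test_matches_dense_normal_equation_solve(self, rng):
        A = rng.normal(size=(10, 10)) + 3 * np.eye(10)
        phi = rng.normal(size=10)
        lam = 0.1
        r = l2cg_solve(A, phi, lam=lam, cg_tol=1e-12)
        direct = np.linalg.solve(A.T @ A + lam * np.eye(10), A.T @ phi)
        err = np.linalg.norm(r.S - direct) / np.linalg.norm(direct)
        assert err <= 1e-8

    def test_nonconvergence_warns_not_raises(self, rng):
        A = rng.normal(size=(30, 30))
        A = A @ A.T + 1e-12 * np.eye(30)  # very ill-conditioned
        with pytest.warns(UserWarning, match="l2-CG"):
            r = l2cg_solve(A, rng.normal(size=30), lam=0.0,
                           cg_tol=1e-14, max_iter=3)
        assert not r.converged


class TestSplitBregman:
    def test_identity_operator_closed_form_prox(self, rng):
        phi = rng.normal(size=30)
        cfg = SolverConfig(mu=0.3, delta=1.0, epsilon=1e-8, max_iter=5000)
        r = l1sb_solve(np.eye(30), phi, cfg)
        assert np.abs(r.S - shrink(phi, 0.3)).max() <= 1e-6

    def test_zero_data_zero_solution(self):
        cfg = SolverConfig(mu=0.5, delta=1.0, max_iter=50)
        r = l1sb_solve(np.eye(4), np.zeros(4), cfg)
        assert not r.S.any()

    def test_beats_l2_solution_on_l1_objective(self, rng):
        A = rng.normal(size=(8, 12))
        phi = rng.normal(size=8)
        mu = 0.1
        cfg = SolverConfig(mu=mu, delta=1.0, epsilon=1e-10, max_iter=5000)
        r_sb = l1sb_solve(A, phi, cfg)
        r_l2 = l2cg_solve(A, phi, lam=mu)
        assert (objective_value(A, phi, r_sb.S, mu)
                <= objective_value(A, phi, r_l2.S, mu) + 1e-8)

    def test_matches_brute_force_on_tiny_instance(self):
        # dense grid refinement over R^2 is an independent minimizer
        # of the l1 objective for n = 2
        A = np.array([[1.0, 0.4], [0.3, 1.2]])
        phi = np.array([1.0, -0.5])
        mu = 0.2
        lo, hi = -2.0 * np.ones(2), 2.0 * np.ones(2)
        for _ in range(6):
            g0 = np.linspace(lo[0], hi[0], 41)
            g1 = np.linspace(lo[1], hi[1], 41)
            G0, G1 = np.meshgrid(g0, g1, indexing="ij")
            S = np.stack([G0.ravel(), G1.ravel()])
            R = A @ S - phi[:, None]
            cost = mu * np.abs(S).sum(axis=0) + 0.5 * (R ** 2).sum(axis=0)
            best = S[:, np.argmin(cost)]
            span = (hi - lo) / 8
            lo, hi = best - span, best + span
        cfg = SolverConfig(mu=mu, delta=1.0, epsilon=1e-12, max_iter=20000)
        r = l1sb_solve(A, phi, cfg)
        assert np.abs(r.S - best).max() < 1e-3
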