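"""Optimization core: Huber machinery, l1-ball projection, primal-dual solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from oracles import (
    objective_reference,
    operator_matrix,
    project_l1_ball_bisect,
    random_tiny_instance,
    solve_reference,
)
from pdcr.optim import (
    SolverConfig,
    estimate_operator_norm,
    huber_dual_prox,
    huber_value,
    objective,
    pd_solve,
    project_l1_ball,
)


class TestHuber:
    @pytest.mark.parametrize(
        "t,delta,expected",
        [(0.5, 1.0, 0.125), (2.0, 1.0, 1.5), (-2.0, 1.0, 1.5), (0.0, 0.3, 0.0)],
    )
    def test_piecewise_values(self, t, delta, expected):
        assert huber_value(t, delta) == pytest.approx(expected)

    def test_continuity_at_knee(self):
        for delta in [0.1, 0.3, 1.0, 2.5]:
            quad = delta**2 / (2 * delta)
            lin = delta - delta / 2
            assert quad == pytest.approx(lin)
            assert huber_value(delta, delta) == pytest.approx(delta / 2)

    def test_l1_bound_on_grid(self):
        # 0 <= h_delta(t) <= |t| and |h_delta(t) - |t|| <= delta/2 everywhere
        t = np.linspace(-10, 10, 4001)
        for delta in [0.05, 0.3, 1.0, 3.0]:
            h = np.array([huber_value(ti, delta) for ti in t])
            assert np.all(h >= 0)
            assert np.all(h <= np.abs(t) + 1e-12)
            assert np.max(np.abs(h - np.abs(t))) <= delta / 2 + 1e-12

    def test_matrix_input_sums_entrywise(self):
        M = np.array([[0.5, 2.0], [-2.0, 0.0]])
        assert huber_value(M, 1.0) == pytest.approx(0.125 + 1.5 + 1.5)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            huber_value(1.0, 0.0)


class TestHuberDualProx:
    def test_zero_fixed_point(self):
        assert huber_dual_prox(np.zeros((2, 2)), 1.0, 1.0).tolist() == [[0, 0], [0, 0]]

    def test_clipping(self):
        assert huber_dual_prox(np.array([10.0]), 1.0, 1.0)[0] == pytest.approx(1.0)
        assert huber_dual_prox(np.array([-10.0]), 1.0, 1.0)[0] == pytest.approx(-1.0)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(200) * 5
        out = huber_dual_prox(z, 0.7, 0.4)
        assert np.all(np.abs(out) <= 1.0)

    def test_against_numerical_prox_of_conjugate(self):
        # h*(z) = delta z^2 / 2 on [-1,1]; prox_{sigma h*}(v) minimizes
        # sigma*delta*z^2/2 + (z-v)^2/2 over [-1,1]
        rng = np.random.default_rng(4)
        for _ in range(50):
            v = float(rng.standard_normal() * 3)
            sigma = float(rng.uniform(0.1, 2.0))
            delta = float(rng.uniform(0.1, 2.0))
            res = minimize_scalar(
                lambda z: sigma * delta * z**2 / 2 + (z - v) ** 2 / 2,
                bounds=(-1.0, 1.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert huber_dual_prox(np.array([v]), sigma, delta)[0] == pytest.approx(
                res.x, abs=1e-6
            )

    def test_moreau_identity(self):
        # prox_{sigma f*}(v) = v - sigma * prox_{f/sigma}(v/sigma) with f = huber
        rng = np.random.default_rng(5)
        for _ in range(30):
            v = float(rng.standard_normal() * 2)
            sigma = float(rng.uniform(0.2, 2.0))
            delta = float(rng.uniform(0.2, 2.0))
            res = minimize_scalar(
                lambda x: huber_value(x, delta) / sigma + (x - v / sigma) ** 2 / 2,
                bounds=(-50, 50),
                method="bounded",
                options={"xatol": 1e-12},
            )
            lhs = huber_dual_prox(np.array([v]), sigma, delta)[0]
            assert lhs == pytest.approx(v - sigma * res.x, abs=1e-6)


class TestProjectL1Ball:
    def test_interior_point_unchanged(self):
        V = np.array([[0.3, -0.2]])
        np.testing.assert_array_equal(project_l1_ball(V, 1.0), V)

    def test_known_projections(self):
        np.testing.assert_allclose(project_l1_ball(np.array([2.0, 0.0]), 1.0), [1.0, 0.0])
        np.testing.assert_allclose(project_l1_ball(np.array([1.0, 1.0]), 1.0), [0.5, 0.5])

    def test_eta_zero_gives_zero(self):
        assert np.all(project_l1_ball(np.array([[1.0, -2.0]]), 0.0) == 0.0)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError):
            project_l1_ball(np.array([1.0]), -0.1)

    def test_matches_bisection_oracle_and_grid(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            v = rng.standard_normal(n) * rng.uniform(0.5, 5)
            eta = float(rng.uniform(0.05, np.abs(v).sum() * 1.2))
            p = project_l1_ball(v, eta)
            ref = project_l1_ball_bisect(v, eta)
            np.testing.assert_allclose(p, ref, atol=1e-8)
            assert np.abs(p).sum() <= eta + 1e-12
            assert np.all(np.sign(p[p != 0]) == np.sign(v[p != 0]))
            # dense threshold grid: no soft-threshold candidate is closer
            best = np.inf
            for theta in np.linspace(0, np.abs(v).max(), 2000):
                cand = np.sign(v) * np.maximum(np.abs(v) - theta, 0)
                if np.abs(cand).sum() <= eta + 1e-9:
                    best = min(best, np.sum((cand - v) ** 2))
            assert np.sum((p - v) ** 2) <= best + 1e-6

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        st.floats(0.01, 10),
    )
    def test_idempotent_and_nonexpansive(self, u, v, eta):
        n = min(len(u), len(v))
        u = np.array(u[:n])
        v = np.array(v[:n])
        pu = project_l1_ball(u, eta)
        pv = project_l1_ball(v, eta)
        np.testing.assert_allclose(project_l1_ball(pu, eta), pu, atol=1e-12)
        assert np.linalg.norm(pu - pv) <= np.linalg.norm(u - v) + 1e-9


class TestOperatorNorm:
    def test_onehot_identity_case(self):
        # X = 0 and Y with each class exactly once: singular values of Y are 1
        X = np.zeros((3, 2))
        Y = np.eye(3)
        assert estimate_operator_norm(X, Y, iters=500, seed=0) == pytest.approx(1.0, rel=1e-6)

    def test_scaled_identity_case(self):
        X = 3.5 * np.eye(4)
        Y = np.zeros((4, 2))
        assert estimate_operator_norm(X, Y, iters=500, seed=0) == pytest.approx(3.5, rel=1e-6)

    def test_matches_dense_svd(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.standard_normal((20, 10))
            y = rng.integers(0, 2, 20)
            Y = np.eye(2)[y]
            true = np.linalg.svd(operator_matrix(X, Y), compute_uv=False)[0]
            est_fast = estimate_operator_norm(X, Y, iters=100, seed=1)
            est_tight = estimate_operator_norm(X, Y, iters=5000, seed=1)
            assert abs(est_fast - true) / true < 0.01
            assert est_tight == pytest.approx(true, abs=1e-6 * true)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((6, 4))
        Y = np.eye(2)[rng.integers(0, 2, 6)]
        a = estimate_operator_norm(X, Y, iters=50, seed=42)
        b = estimate_operator_norm(X, Y, iters=50, seed=42)
        assert a == b

    def test_invalid_iters(self):
        with pytest.raises(ValueError):
            estimate_operator_norm(np.ones((2, 2)), np.ones((2, 2)), iters=0)


class TestObjective:
    def test_onehot_structure_at_reference_point(self):
        # W = 0, mu = I: residual is Y itself, one unit entry per row
        rng = np.random.default_rng(9)
        m, d, k = 8, 5, 2
        X = rng.standard_normal((m, d))
        Y = np.eye(k)[rng.integers(0, k, m)]
        cfg = SolverConfig(delta=0.4)
        expected = m * huber_value(1.0, 0.4)
        assert objective(np.zeros((d, k)), np.eye(k), X, Y, cfg) == pytest.approx(expected)

    def test_zero_at_perfect_fit(self):
        # mu = I and X W = Y exactly: loss and penalty both vanish
        Y = np.eye(2)[[0, 1, 0, 1]]
        X = Y.copy()  # d = k = 2
        W = np.eye(2)
        cfg = SolverConfig()
        assert objective(W, np.eye(2), X, Y, cfg) == pytest.approx(0.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(10)
        for loss in ["huber", "squared_l2"]:
            X, Y = random_tiny_instance(rng)
            d, k = X.shape[1], 2
            W = rng.standard_normal((d, k))
            mu = rng.standard_normal((k, k))
            cfg = SolverConfig(delta=0.3, rho_penalty=1.7, loss=loss)
            ref = objective_reference(W, mu, X, Y, 0.3, 1.7, loss)
            assert objective(W, mu, X, Y, cfg) == pytest.approx(ref, rel=1e-12)

    def test_shape_mismatch(self):
        cfg = SolverConfig()
        with pytest.raises(ValueError, match="shapes"):
            objective(np.zeros((3, 2)), np.eye(2), np.zeros((4, 5)), np.eye(4), cfg)


class TestPdSolve:
    def test_eta_zero_closed_form_mu(self):
        # W forced to 0; each mu_jl decouples:
        #   min n_j h_delta(mu) + rho/2 (I_jl - mu)^2
        # quadratic branch optimum: mu_jl = rho I_jl / (n_j/delta + rho)
        rng = np.random.default_rng(11)
        X = rng.standard_normal((9, 4))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1])
        Y = np.eye(2)[y]
        delta, rho = 0.3, 1.0
        cfg = SolverConfig(eta=0.0, delta=delta, rho_penalty=rho, max_iter=20000, tol=1e-12)
        res = pd_solve(X, Y, cfg)
        assert np.all(res.W == 0.0)
        n = np.array([4.0, 5.0])
        expected = np.diag(rho / (n / delta + rho))
        assert np.all(np.abs(expected) <= delta)  # quadratic-branch regime
        np.testing.assert_allclose(res.mu, expected, atol=1e-5)
        # cross-check against scalar numerical minimization
        from scipy.optimize import minimize_scalar

        for j in range(2):
            for l in range(2):
                target = 1.0 if j == l else 0.0
                r = minimize_scalar(
                    lambda t: n[j] * huber_value(t, delta) + rho / 2 * (target - t) ** 2,
                    bounds=(-2, 2),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                assert res.mu[j, l] == pytest.approx(r.x, abs=1e-5)

    def test_matches_projected_gradient_oracle_tiny(self):
        rng = np.random.default_rng(12)
        X, Y = random_tiny_instance(rng, m_max=6, d_max=3)
        eta = 10.0
        cfg = SolverConfig(eta=eta, max_iter=30000, tol=1e-13)
        res = pd_solve(X, Y, cfg)
        obj = objective(res.W, res.mu, X, Y, cfg)
        _, _, ref = solve_reference(X, Y, eta, cfg.delta, cfg.rho_penalty, iters=40000)
        assert abs(obj - ref) <= 1e-4

    def test_feasible_at_every_iterate(self):
        rng = np.random.default_rng(13)
        X, Y = random_tiny_instance(rng)
        cfg = SolverConfig(eta=0.7, max_iter=500)
        res = pd_solve(X, Y, cfg)
        assert all(l1 <= 0.7 + 1e-9 for l1 in res.w_l1_trace)
        assert np.abs(res.W).sum() <= 0.7 + 1e-9

    def test_improves_on_reference_point(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            X, Y = random_tiny_instance(rng)
            cfg = SolverConfig(eta=1.5, max_iter=5000, tol=1e-10)
            res = pd_solve(X, Y, cfg)
            k = Y.shape[1]
            at_ref = objective(np.zeros((X.shape[1], k)), np.eye(k), X, Y, cfg)
            assert objective(res.W, res.mu, X, Y, cfg) <= at_ref + 1e-12

    def test_objective_nonincreasing_in_eta(self):
        rng = np.random.default_rng(15)
        X, Y = random_tiny_instance(rng)
        objs = []
        for eta in [0.0, 0.5, 1.0, 2.0, 1e6]:
            cfg = SolverConfig(eta=eta, max_iter=20000, tol=1e-12)
            res = pd_solve(X, Y, cfg)
            objs.append(objective(res.W, res.mu, X, Y, cfg))
        assert all(a >= b - 1e-6 for a, b in zip(objs, objs[1:]))

    def test_duplicate_columns_share_total_weight(self):
        rng = np.random.default_rng(16)
        X, Y = random_tiny_instance(rng, m_max=8, d_max=4)
        Xdup = np.hstack([X, X[:, [0]]])  # duplicate the first feature
        cfg = SolverConfig(eta=1.0, max_iter=40000, tol=1e-13)
        res_base = pd_solve(X, Y, cfg)
        res_dup = pd_solve(Xdup, Y, cfg)
        w_base = np.abs(res_base.W[0]).sum()
        w_dup = np.abs(res_dup.W[0]).sum() + np.abs(res_dup.W[-1]).sum()
        assert w_dup == pytest.approx(w_base, abs=1e-3)

    def test_squared_l2_branch_agrees_with_huber_for_large_delta(self):
        # for delta exceeding every residual, h_delta(t) = t^2/(2 delta):
        # the huber objective equals the squared_l2 objective / delta
        rng = np.random.default_rng(17)
        X, Y = random_tiny_instance(rng)
        d, k = X.shape[1], 2
        W = 0.01 * rng.standard_normal((d, k))
        mu = np.eye(k) + 0.01 * rng.standard_normal((k, k))
        big_delta = 1e3
        cfg_h = SolverConfig(delta=big_delta, rho_penalty=1.0, loss="huber")
        cfg_2 = SolverConfig(delta=0.3, rho_penalty=1.0, loss="squared_l2")
        R = Y @ mu - X @ W
        assert np.max(np.abs(R)) < big_delta
        pen = 0.5 * np.sum((np.eye(k) - mu) ** 2)
        loss_h = objective(W, mu, X, Y, cfg_h) - pen
        loss_2 = objective(W, mu, X, Y, cfg_2) - pen
        assert loss_h == pytest.approx(loss_2 / big_delta, rel=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(18)
        X, Y = random_tiny_instance(rng)
        cfg = SolverConfig(eta=1.0, max_iter=200)
        r1 = pd_solve(X, Y, cfg)
        r2 = pd_solve(X, Y, cfg)
        assert np.array_equal(r1.W, r2.W) and np.array_equal(r1.mu, r2.mu)

    def test_step_size_condition_under_auto_steps(self):
        rng = np.random.default_rng(19)
        X, Y = random_tiny_instance(rng)
        L = estimate_operator_norm(X, Y, iters=500, seed=0)
        sigma = tau = 0.99 / L
        assert sigma * tau * L**2 <= 1.0 + 1e-12


class TestSolverConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta": 0.0},
            {"rho_penalty": -1.0},
            {"eta": -0.5},
            {"loss": "hinge"},
            {"max_iter": 0},
            {"tol": 0.0},
            {"auto_steps": False, "sigma": None, "tau": 0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
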