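"""FOCUSS family, GCV scoring and golden-section search against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import optimize

from pulsedecon import (
    KineticParams,
    PulseTrain,
    SparseSolverConfig,
    build_forward_operator,
    focuss_plus,
    focuss_step,
    forward_simulate,
    gcv_focuss_plus,
    gcv_score,
    golden_section_min,
)
from pulsedecon.sparse_recovery import GCVWorkspace, build_gcv_workspace, sparsity


def best_subset_nnls(A: np.ndarray, y: np.ndarray, k_max: int):
    """Exhaustive nonnegative best-subset oracle: least residual over all supports."""
    n = A.shape[1]
    best = (np.linalg.norm(y), np.zeros(n))
    for k in range(1, k_max + 1):
        for support in itertools.combinations(range(n), k):
            coef, resid = optimize.nnls(A[:, support], y)
            if resid < best[0]:
                u = np.zeros(n)
                u[list(support)] = coef
                best = (resid, u)
    return best


class TestFocussStep:
    def test_identity_system_returns_data(self):
        y = np.array([0.3, -1.2, 2.0])
        u = focuss_step(np.eye(3), y, np.ones(3), p=0.5, lam=0.0)
        assert np.allclose(u, y, atol=1e-10)

    def test_zero_entries_are_absorbing(self):
        rng = np.random.default_rng(5)
        A = np.abs(rng.normal(size=(4, 8)))
        y = np.abs(rng.normal(size=4))
        u = np.ones(8)
        u[[1, 4, 6]] = 0.0
        for _ in range(10):
            u = focuss_step(A, y, u, p=0.5, lam=1e-6)
            assert np.all(u[[1, 4, 6]] == 0.0)

    def test_small_system_reaches_best_subset_quality(self):
        A = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        y = np.array([1.0, 1.0])
        u = np.ones(3)
        for _ in range(50):
            u = np.clip(focuss_step(A, y, u, p=0.5, lam=1e-9), 0.0, None)
        resid = np.linalg.norm(y - A @ u)
        best_resid, _ = best_subset_nnls(A, y, 2)
        assert resid <= best_resid + 1e-6
        # lp-sparsest representation of (1,1) in this dictionary is the single third atom
        assert np.sum(np.abs(u) ** 0.5) <= 2 * 1.0 + 1e-3

    def test_singular_unregularized_system_raises(self):
        A = np.ones((3, 4))  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            focuss_step(A, np.array([1.0, 2.0, 3.0]), np.ones(4), p=0.5, lam=0.0)


class TestFocussPlus:
    def test_contract_nonnegative_and_capped(self):
        rng = np.random.default_rng(11)
        A = np.abs(rng.normal(size=(30, 300)))
        y = np.abs(rng.normal(size=30)) * 5
        u = focuss_plus(A, y, SparseSolverConfig(n_max=22))
        assert u.min() >= 0.0
        assert sparsity(u) <= 22

    def test_recovers_single_dominant_pulse(self, theta_ref):
        tr = PulseTrain(np.array([300]), np.array([20.0]))
        y = forward_simulate(theta_ref, tr, y0=0.0, M=144, dt=10.0)
        op = build_forward_operator(theta_ref, M=144, N=1440, dt=10.0)
        u = focuss_plus(op.A, y)
        assert abs(int(np.argmax(u)) - 300) <= 1

    def test_all_zero_observations_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            u = focuss_plus(np.abs(np.random.default_rng(0).normal(size=(5, 20))), np.zeros(5))
        assert np.all(u == 0)


class TestGCV:
    def test_zero_operator_score_is_mean_square(self):
        y = np.array([1.0, 2.0, 2.0])
        ws = build_gcv_workspace(np.zeros((3, 0)), y)
        assert gcv_score(ws, 0.7) == pytest.approx(float(y @ y) / 3)

    @pytest.mark.parametrize("lam", [1e-4, 0.5, 3.0])
    def test_svd_form_matches_influence_matrix(self, lam):
        rng = np.random.default_rng(42)
        Aw = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        # direct route: build H explicitly from the ridge normal equations
        H = Aw @ np.linalg.solve(Aw.T @ Aw + lam * np.eye(6), Aw.T)
        L = 4
        direct = L * float(np.sum(((np.eye(L) - H) @ y) ** 2)) / np.trace(np.eye(L) - H) ** 2
        assert gcv_score(build_gcv_workspace(Aw, y), lam) == pytest.approx(direct, rel=1e-10)

    def test_residual_term_nondecreasing_in_lambda(self):
        rng = np.random.default_rng(7)
        ws = build_gcv_workspace(rng.normal(size=(5, 9)), rng.normal(size=5))
        lams = np.linspace(1e-6, 10, 50)

        def resid(lam):
            s2 = ws.singular_values**2
            return float(np.sum(((lam / (s2 + lam)) * ws.projected_data) ** 2))

        vals = [resid(l) for l in lams]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_workspace_validates_ordering(self):
        with pytest.raises(ValueError):
            GCVWorkspace(np.array([1.0, 2.0]), np.zeros(2), 0.0, 4)


class TestGoldenSection:
    def test_quadratic(self):
        assert golden_section_min(lambda x: (x - 3.0) ** 2, 0.0, 10.0, 1e-6) == pytest.approx(3.0, abs=1e-5)

    def test_monotone_hits_boundary(self):
        assert golden_section_min(lambda x: x, 0.0, 10.0, 1e-6) == pytest.approx(0.0, abs=1e-5)
        assert golden_section_min(lambda x: -x, 0.0, 10.0, 1e-6) == pytest.approx(10.0, abs=1e-5)

    def test_agrees_with_grid_scan_on_gcv(self):
        rng = np.random.default_rng(19)
        ws = build_gcv_workspace(rng.normal(size=(6, 10)), rng.normal(size=6))
        f = lambda lam: gcv_score(ws, lam)
        xstar = golden_section_min(f, 1e-8, 10.0, 1e-6)
        grid = np.linspace(1e-8, 10.0, 100_000)
        gstar = grid[int(np.argmin([f(g) for g in grid]))]
        assert abs(xstar - gstar) <= (grid[1] - grid[0]) + 1e-6


class TestGCVFocussPlus:
    def test_noise_free_support_and_amplitudes(self, theta_ref, separated_train):
        y = forward_simulate(theta_ref, separated_train, y0=0.0, M=144, dt=10.0)
        op = build_forward_operator(theta_ref, M=144, N=1440, dt=10.0)
        u, lam = gcv_focuss_plus(op.A, y)
        tr = PulseTrain.from_dense(u)
        assert len(tr) == len(separated_train)
        assert np.max(np.abs(tr.times - separated_train.times)) <= 1
        assert np.allclose(tr.amplitudes, separated_train.amplitudes, rtol=0.01)

    def test_scale_covariance(self, theta_ref, separated_train):
        y = forward_simulate(theta_ref, separated_train, y0=0.0, M=144, dt=10.0)
        y = y + np.random.default_rng(2).normal(0, 0.3, size=144)
        op = build_forward_operator(theta_ref, M=144, N=1440, dt=10.0)
        u1, _ = gcv_focuss_plus(op.A, y)
        c = 3.7
        u2, _ = gcv_focuss_plus(op.A, c * y)
        assert np.allclose(u2, c * u1, rtol=1e-4, atol=1e-8)

    def test_sparsity_band_under_noise(self, theta_ref, separated_train):
        rng = np.random.default_rng(8)
        y = forward_simulate(theta_ref, separated_train, y0=0.0, M=144, dt=10.0)
        op = build_forward_operator(theta_ref, M=144, N=1440, dt=10.0)
        u, _ = gcv_focuss_plus(op.A, y + rng.normal(0, 0.45, 144))
        assert 13 <= sparsity(u) <= 22  # 15-22 targets, paper-reported count error <= 2

    def test_fixed_point_stationarity(self, theta_ref, separated_train):
        """At convergence the returned u is a fixed point of its own update."""
        y = forward_simulate(theta_ref, separated_train, y0=0.0, M=144, dt=10.0)
        op = build_forward_operator(theta_ref, M=144, N=1440, dt=10.0)
        cfg = SparseSolverConfig()
        u, lam = gcv_focuss_plus(op.A, y, cfg)
        u_next = np.clip(focuss_step(op.A, y, u, cfg.p, lam), 0.0, None)
        assert np.linalg.norm(u_next - u) / np.linalg.norm(u) < 1e-3
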