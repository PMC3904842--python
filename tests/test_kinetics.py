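"""Two-compartment kernel, forward operator and simulation against an ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsedecon import (
    KineticParams,
    PulseTrain,
    build_forward_operator,
    forward_simulate,
    impulse_response,
)
from pulsedecon.kinetics import CortisolSeries, impulse_response_jac

from conftest import rk4_two_compartment


class TestKineticParams:
    def test_cone_is_enforced(self):
        with pytest.raises(ValueError):
            KineticParams(0.02, 0.01)  # theta1 < 4*theta2
        with pytest.raises(ValueError):
            KineticParams(0.05, -0.001)
        with pytest.raises(ValueError):
            KineticParams(0.0, 0.0)
        KineticParams(0.04, 0.01)  # boundary is feasible

    def test_cone_excludes_degenerate_kernel(self):
        th = KineticParams(0.04, 0.01)
        assert th.theta1 != th.theta2


class TestPulseTrain:
    def test_dense_roundtrip_drops_dust(self):
        u = np.zeros(100)
        u[[3, 50]] = [5.0, 2.0]
        u[70] = 1e-9  # below the relative dust threshold
        tr = PulseTrain.from_dense(u)
        assert list(tr.times) == [3, 50]
        assert np.allclose(tr.dense()[[3, 50]], [5.0, 2.0])

    def test_rejects_unsorted_and_nonpositive(self):
        with pytest.raises(ValueError):
            PulseTrain(np.array([5, 3]), np.array([1.0, 1.0]), n_grid=10)
        with pytest.raises(ValueError):
            PulseTrain(np.array([3, 5]), np.array([1.0, 0.0]), n_grid=10)


class TestImpulseResponse:
    def test_zero_lag_and_decay(self, theta_ref):
        assert impulse_response(theta_ref, 0.0) == 0.0
        assert impulse_response(theta_ref, 10.0) > 0.0
        assert impulse_response(theta_ref, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_negative_lag_rejected(self, theta_ref):
        with pytest.raises(ValueError):
            impulse_response(theta_ref, -1.0)

    def test_matches_rk4_oracle_at_lag_10(self, theta_ref):
        oracle = rk4_two_compartment(theta_ref.theta1, theta_ref.theta2,
                                     [(0.0, 1.0)], t_end=10.0)
        assert impulse_response(theta_ref, 10.0) == pytest.approx(oracle, rel=1e-6)

    def test_jacobian_matches_finite_differences(self, theta_ref):
        lag = np.array([5.0, 30.0, 120.0])
        d1, d2 = impulse_response_jac(theta_ref, lag)
        eps = 1e-7
        for i, (dd, which) in enumerate([(d1, "theta1"), (d2, "theta2")]):
            hi = dict(theta1=theta_ref.theta1, theta2=theta_ref.theta2)
            lo = dict(hi)
            hi[which] += eps
            lo[which] -= eps
            fd = (impulse_response(KineticParams(**hi), lag)
                  - impulse_response(KineticParams(**lo), lag)) / (2 * eps)
            assert np.allclose(dd, fd, rtol=1e-5)


class TestForwardOperator:
    def test_causality_structure(self, theta_ref):
        op = build_forward_operator(theta_ref, M=144, N=1440, dt=10.0)
        assert op.A.shape == (144, 1440)
        # row 0 samples t=10: responds to impulses at minutes 0..9 only
        assert np.all(op.A[0, :10] > 0)
        assert np.all(op.A[0, 10:] == 0)
        assert np.all(op.A >= 0) and np.all(op.b >= 0)

    def test_first_entry_matches_oracle(self, theta_ref):
        op = build_forward_operator(theta_ref, M=4, N=40, dt=10.0)
        oracle = rk4_two_compartment(theta_ref.theta1, theta_ref.theta2,
                                     [(0.0, 1.0)], t_end=10.0)
        assert op.A[0, 0] == pytest.approx(oracle, rel=1e-6)

    def test_toeplitz_in_lag(self, theta_ref):
        op = build_forward_operator(theta_ref, M=6, N=60, dt=10.0)
        # entry depends only on t_k - tau_i
        assert op.A[1, 10] == pytest.approx(op.A[0, 0], rel=1e-12)
        assert op.A[3, 25] == pytest.approx(op.A[2, 15], rel=1e-12)

    def test_zero_input_is_pure_decay(self, theta_ref):
        op = build_forward_operator(theta_ref, M=12, N=120, dt=10.0)
        y = op.apply(np.zeros(120), y0=7.3)
        t_k = 10.0 * np.arange(1, 13)
        assert np.allclose(y, 7.3 * np.exp(-theta_ref.theta2 * t_k), rtol=1e-12)

    def test_bad_grid_rejected(self, theta_ref):
        with pytest.raises(ValueError):
            build_forward_operator(theta_ref, M=0, N=10)
        with pytest.raises(ValueError):
            build_forward_operator(theta_ref, M=10, N=10, dt=0.0)


class TestForwardSimulate:
    def test_empty_train_gives_zero(self, theta_ref):
        tr = PulseTrain(np.empty(0, dtype=int), np.empty(0))
        assert np.all(forward_simulate(theta_ref, tr, y0=0.0) == 0.0)

    def test_single_pulse_is_shifted_kernel(self, theta_ref):
        tr = PulseTrain(np.array([37]), np.array([4.2]))
        y = forward_simulate(theta_ref, tr, y0=0.0, M=20, dt=10.0)
        t_k = 10.0 * np.arange(1, 21)
        expected = np.where(t_k > 37, 4.2 * impulse_response(theta_ref, np.maximum(t_k - 37, 0)), 0.0)
        assert np.allclose(y, expected, rtol=1e-12)

    def test_matches_rk4_on_full_train(self, theta_ref, separated_train):
        y = forward_simulate(theta_ref, separated_train, y0=5.0, M=144, dt=10.0)
        pulses = list(zip(separated_train.times.tolist(), separated_train.amplitudes.tolist()))
        for k in [0, 30, 143]:  # spot-check sample times across the day
            t_end = 10.0 * (k + 1)
            within = [(t, q) for t, q in pulses if t < t_end]
            oracle = rk4_two_compartment(theta_ref.theta1, theta_ref.theta2, within, t_end)
            oracle += 5.0 * np.exp(-theta_ref.theta2 * t_end)
            assert y[k] == pytest.approx(oracle, rel=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_superposition(self, seed):
        rng = np.random.default_rng(seed)
        t2 = rng.uniform(0.002, 0.02)
        theta = KineticParams(rng.uniform(4 * t2, 0.2), t2)
        times = np.sort(rng.choice(200, size=6, replace=False))
        a1, a2 = rng.uniform(0.5, 5.0, (2, 6))
        tr1 = PulseTrain(times, a1, n_grid=240)
        tr2 = PulseTrain(times, a2, n_grid=240)
        tr12 = PulseTrain(times, a1 + a2, n_grid=240)
        kw = dict(y0=0.0, M=24, dt=10.0)
        assert np.allclose(
            forward_simulate(theta, tr12, **kw),
            forward_simulate(theta, tr1, **kw) + forward_simulate(theta, tr2, **kw),
            rtol=1e-10,
        )


def test_series_validation():
    with pytest.raises(ValueError):
        CortisolSeries(y0=5.0, values=np.array([1.0, np.nan]))
    with pytest.raises(ValueError):
        CortisolSeries(y0=5.0, values=np.array([1.0]), dt=-1.0)
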