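"""Two-compartment cortisol kinetics.

Serum cortisol is modelled by first-order transfer of hormone from the
adrenal compartment into blood (infusion rate ``theta1``, 1/min) and
first-order elimination from blood by the liver (clearance rate
``theta2``, 1/min).  Secretory events are impulses of amount ``q`` landing
in the adrenal compartment at integer minutes; each contributes the
bi-exponential response

    h(t) = theta1 / (theta1 - theta2) * (exp(-theta2 t) - exp(-theta1 t))

to the serum concentration.  Sampling the superposition of all impulses
plus the decaying initial serum level ``y0`` on the coarse observation
grid gives the linear system ``y = A(theta) u + b(theta) y0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "KineticParams",
    "PulseTrain",
    "CortisolSeries",
    "ForwardOperator",
    "impulse_response",
    "build_forward_operator",
    "forward_simulate",
]

#: input grid length: one candidate impulse slot per minute over 24 h
N_MINUTES = 1440
#: observation spacing in minutes
DEFAULT_DT = 10.0
#: relative threshold below which an input entry is numerical dust, not a pulse
DUST_RTOL = 1e-6


@dataclass(frozen=True)
class KineticParams:
    """Infusion/clearance rate pair constrained to the cone theta1 >= 4*theta2 > 0.

    The cone encodes the physiological assumption that transfer out of the
    adrenal glands is much faster than elimination from blood; it also keeps
    theta1 != theta2 so the bi-exponential response is never degenerate.
    """

    theta1: float
    theta2: float

    def __post_init__(self) -> None:
        if not (self.theta2 > 0.0 and self.theta1 > 0.0):
            raise ValueError(f"rates must be positive, got ({self.theta1}, {self.theta2})")
        if self.theta1 < 4.0 * self.theta2:
            raise ValueError(
                f"infusion rate must be at least four times the clearance rate: "
                f"theta1={self.theta1} < 4*theta2={4.0 * self.theta2}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2], dtype=float)


@dataclass(frozen=True)
class PulseTrain:
    """Sparse nonnegative input: event minutes and amounts on a 1-min grid.

    ``times`` are strictly increasing integers in [0, n_grid - 1];
    ``amplitudes`` are the delivered amounts (all > 0; zeros are not stored).
    """

    times: np.ndarray
    amplitudes: np.ndarray
    n_grid: int = N_MINUTES

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=int)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be 1-D arrays of equal length")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.n_grid:
                raise ValueError(f"event times must lie in [0, {self.n_grid - 1}]")
            if np.any(a <= 0):
                raise ValueError("stored amplitudes must be strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_pulses(self) -> int:
        return len(self)

    def dense(self) -> np.ndarray:
        """Length-``n_grid`` vector with amplitudes at event minutes, zero elsewhere."""
        u = np.zeros(self.n_grid)
        u[self.times] = self.amplitudes
        return u

    @classmethod
    def from_dense(cls, u: np.ndarray, rtol: float = DUST_RTOL) -> "PulseTrain":
        """Extract events from a dense input vector, discarding numerical dust.

        An entry counts as a pulse iff it exceeds ``rtol * max(u)``.
        """
        u = np.asarray(u, dtype=float)
        if u.ndim != 1:
            raise ValueError("dense input must be 1-D")
        peak = u.max(initial=0.0)
        if peak <= 0:
            return cls(np.empty(0, dtype=int), np.empty(0), n_grid=u.size)
        idx = np.flatnonzero(u > rtol * peak)
        return cls(idx, u[idx], n_grid=u.size)


@dataclass(frozen=True)
class CortisolSeries:
    """One initial serum sample plus M samples at fixed spacing.

    ``y0`` is the concentration at t=0; ``values[k]`` the concentration at
    t = dt*(k+1) minutes.  ``sigma_nu`` is the (optional) assay-noise
    standard deviation in the same concentration units.
    """

    y0: float
    values: np.ndarray
    dt: float = DEFAULT_DT
    sigma_nu: Optional[float] = None
    unit: str = "ug/dL"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a 1-D array with at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite (interpolate missing points at load time)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma_nu is not None and self.sigma_nu < 0:
            raise ValueError("sigma_nu must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def sample_times(self) -> np.ndarray:
        """Observation times t_k = dt*(k+1), excluding t=0."""
        return self.dt * np.arange(1, self.n_samples + 1)


def impulse_response(theta: KineticParams, lag) -> np.ndarray | float:
    """Serum response at ``lag`` minutes to a unit impulse into the adrenal pool.

    h(0) = 0: an impulse delivers mass to the adrenal compartment, which has
    zero instantaneous effect on blood.  Vectorized over ``lag``.
    """
    lag_arr = np.asarray(lag, dtype=float)
    if np.any(lag_arr < 0):
        raise ValueError("lag must be nonnegative")
    t1, t2 = theta.theta1, theta.theta2
    h = t1 / (t1 - t2) * (np.exp(-t2 * lag_arr) - np.exp(-t1 * lag_arr))
    return h if lag_arr.ndim else float(h)


def impulse_response_jac(theta: KineticParams, lag) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives (dh/dtheta1, dh/dtheta2) of the kernel at ``lag``."""
    lag = np.asarray(lag, dtype=float)
    t1, t2 = theta.theta1, theta.theta2
    d = t1 - t2
    e1 = np.exp(-t1 * lag)
    e2 = np.exp(-t2 * lag)
    dh1 = -t2 / d**2 * (e2 - e1) + t1 / d * lag * e1
    dh2 = t1 / d**2 * (e2 - e1) - t1 / d * lag * e2
    return dh1, dh2


@dataclass(frozen=True)
class ForwardOperator:
    """Discretized forward map: samples = A @ u_dense + b * y0.

    ``A[k, i]`` is the response at sample time t_k = dt*(k+1) to a unit impulse
    at minute i (zero for i >= t_k, causality); ``b[k] = exp(-theta2 t_k)``
    propagates the initial serum level.  A is Toeplitz in the lag t_k - i.
    """

    A: np.ndarray
    b: np.ndarray
    theta: KineticParams
    dt: float = DEFAULT_DT
    kernel: np.ndarray = field(default=None, repr=False)  # h on the 1-min lag grid

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def n_grid(self) -> int:
        return self.A.shape[1]

    def apply(self, u_dense: np.ndarray, y0: float = 0.0) -> np.ndarray:
        return self.A @ np.asarray(u_dense, dtype=float) + self.b * y0


def build_forward_operator(
    theta: KineticParams,
    M: int = 144,
    N: int = N_MINUTES,
    dt: float = DEFAULT_DT,
) -> ForwardOperator:
    """Assemble A (M x N) and b (length M) for the given kinetics.

    Exploits the Toeplitz lag structure: h is evaluated once on the integer
    lag grid and gathered into A.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be at least 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_k = dt * np.arange(1, M + 1)
    lags = t_k[:, None] - np.arange(N)[None, :]
    causal = lags > 0
    kernel_lags = np.where(causal, lags, 0.0)
    A = np.where(causal, impulse_response(theta, kernel_lags), 0.0)
    b = np.exp(-theta.theta2 * t_k)
    h_grid = impulse_response(theta, np.arange(N + 1, dtype=float))
    return ForwardOperator(A=A, b=b, theta=theta, dt=dt, kernel=h_grid)


def forward_simulate(
    theta: KineticParams,
    pulses: PulseTrain,
    y0: float = 0.0,
    M: int = 144,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Noise-free sample vector at t = dt, 2*dt, ..., M*dt.

    Superposition of the bi-exponential responses of all pulses plus the
    exponentially decaying initial condition.  Only the pulse support is
    touched, so this is cheap even on the full 1440-slot grid.
    """
    t_k = dt * np.arange(1, M + 1)
    y = y0 * np.exp(-theta.theta2 * t_k)
    if len(pulses):
        lags = t_k[:, None] - pulses.times[None, :]
        contrib = np.where(lags > 0, impulse_response(theta, np.maximum(lags, 0.0)), 0.0)
        y = y + contrib @ pulses.amplitudes
    return y
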