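"""Shared fixtures: reference kinetics and small simulated series."""

import numpy as np
import pytest

from pulsedecon import CortisolSeries, KineticParams, PulseTrain, generate_dataset


@pytest.fixture(scope="session")
def theta_ref() -> KineticParams:
    """Published kinetics of reference subject 1 (infusion 0.0739, clearance 0.0067)."""
    return KineticParams(0.0739, 0.0067)


@pytest.fixture(scope="session")
def separated_train() -> PulseTrain:
    """18 well-separated pulses (78 min apart) with moderate amplitudes."""
    times = np.arange(18) * 78 + 20
    amps = np.random.default_rng(0).uniform(2.0, 10.0, 18)
    return PulseTrain(times, amps)


@pytest.fixture(scope="session")
def noiseless_series(theta_ref, separated_train) -> CortisolSeries:
    return generate_dataset(theta_ref, separated_train, y0=5.0, sigma_nu=0.0, seed=1)


def rk4_two_compartment(theta1: float, theta2: float, pulses, t_end: float,
                        step: float = 0.01) -> float:
    """Independent numeric oracle: classic fixed-step RK4 on the two-state system.

    dx1/dt = -theta1 x1 + impulses, dx2/dt = theta1 x1 - theta2 x2, both
    compartments starting empty; ``pulses`` is a list of (time, amount)
    added to x1 when the integration reaches that time.  Returns x2(t_end).
    """
    n = int(round(t_end / step))
    x1 = 0.0
    x2 = 0.0
    remaining = sorted(pulses)

    def f(x1, x2):
        return -theta1 * x1, theta1 * x1 - theta2 * x2

    for k in range(n):
        t = k * step
        while remaining and abs(remaining[0][0] - t) < step / 2:
            x1 += remaining.pop(0)[1]
        k1a, k1b = f(x1, x2)
        k2a, k2b = f(x1 + step / 2 * k1a, x2 + step / 2 * k1b)
        k3a, k3b = f(x1 + step / 2 * k2a, x2 + step / 2 * k2b)
        k4a, k4b = f(x1 + step * k3a, x2 + step * k3b)
        x1 += step / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
        x2 += step / 6 * (k1b + 2 * k2b + 2 * k3b + k4b)
    return x2
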