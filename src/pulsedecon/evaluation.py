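"""Scoring recovered pulse trains and kinetic parameters against ground truth.

A recovered train is compared to the simulated truth by greedy one-to-one
matching: candidate pairs within a time window are taken in increasing
order of |time difference| (ties to the earlier true minute, then the
earlier estimated minute).  Matched pairs give the maximum timing error
M_e; leftover true pulses are undetected (N_u) and leftover estimated
pulses are extras (N_d).  The 30-min default window is a convention: it
comfortably covers the worst timing errors seen in practice, and how to
distinguish a mistimed pulse from an extra one is otherwise arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .driver import DeconResult
from .kinetics import KineticParams, PulseTrain

__all__ = ["RecoveryMetrics", "match_pulses", "evaluate_recovery", "percent_error"]

DEFAULT_WINDOW_MIN = 30.0


@dataclass(frozen=True)
class RecoveryMetrics:
    """Per-dataset recovery scores."""

    max_timing_error: float  # M_e, minutes over matched pairs (0 if none matched)
    n_undetected: int        # N_u
    n_extra: int             # N_d
    pulse_count_error: int   # |N_hat - N|
    theta1_pct_error: Optional[float] = None
    theta2_pct_error: Optional[float] = None
    r_squared: Optional[float] = None
    window: float = DEFAULT_WINDOW_MIN


def percent_error(estimate: float, truth: float) -> float:
    """100 * |estimate - truth| / truth."""
    if truth == 0:
        raise ZeroDivisionError("percent error undefined for zero truth")
    return 100.0 * abs(estimate - truth) / abs(truth)


def match_pulses(
    true: PulseTrain,
    est: PulseTrain,
    window: float = DEFAULT_WINDOW_MIN,
) -> tuple[list[tuple[int, int]], RecoveryMetrics]:
    """Greedy one-to-one matching of estimated to true pulses within a window.

    Returns the matched (true_index, est_index) pairs and the count metrics.
    Deterministic: ties in distance break to the earlier true minute, then
    the earlier estimated minute.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t_times = true.times
    e_times = est.times
    pairs = [
        (abs(int(tt) - int(et)), i, j)
        for i, tt in enumerate(t_times)
        for j, et in enumerate(e_times)
        if abs(int(tt) - int(et)) <= window
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_e: set[int] = set()
    matched: list[tuple[int, int]] = []
    for dist, i, j in pairs:
        if i in used_t or j in used_e:
            continue
        used_t.add(i)
        used_e.add(j)
        matched.append((i, j))
    max_err = max((abs(int(t_times[i]) - int(e_times[j])) for i, j in matched), default=0)
    metrics = RecoveryMetrics(
        max_timing_error=float(max_err),
        n_undetected=len(t_times) - len(matched),
        n_extra=len(e_times) - len(matched),
        pulse_count_error=abs(len(e_times) - len(t_times)),
        window=window,
    )
    return matched, metrics


def evaluate_recovery(
    truth: tuple[KineticParams, PulseTrain],
    result: DeconResult,
    window: float = DEFAULT_WINDOW_MIN,
) -> RecoveryMetrics:
    """Assemble the full metric set for one deconvolution against its truth."""
    theta_true, pulses_true = truth
    _, m = match_pulses(pulses_true, result.pulses_hat, window=window)
    return RecoveryMetrics(
        max_timing_error=m.max_timing_error,
        n_undetected=m.n_undetected,
        n_extra=m.n_extra,
        pulse_count_error=abs(result.n_pulses - len(pulses_true)),
        theta1_pct_error=percent_error(result.theta_hat.theta1, theta_true.theta1),
        theta2_pct_error=percent_error(result.theta_hat.theta2, theta_true.theta2),
        r_squared=result.r_squared,
        window=window,
    )
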