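"""CSV/JSON/YAML plumbing: series and pulse-train readers/writers, results, truth.

Interchange conventions
-----------------------
* series CSV: columns ``time_min,concentration``; the first row is t=0 (the
  initial sample y0); remaining rows sit on a uniform grid.  Interior
  missing rows or NaN concentrations are linearly interpolated at load
  time; leading/trailing gaps are errors.
* pulse CSV: columns ``time_min,amplitude``, times ascending.
* results/truth/metrics: JSON; every artifact embeds the seed and a hash
  of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .driver import DeconResult
from .kinetics import CortisolSeries, KineticParams, PulseTrain
from .sparse_recovery import SparseSolverConfig
from .synthetic import PulseGenConfig

__all__ = [
    "read_series",
    "write_series",
    "read_pulses",
    "write_pulses",
    "write_result",
    "read_result",
    "write_truth",
    "read_truth",
    "load_run_config",
    "config_hash",
]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line where known."""


def read_series(path, dt: float = 10.0, sigma_nu: Optional[float] = None) -> CortisolSeries:
    """Load a series CSV onto the uniform grid, interpolating interior gaps."""
    df = pd.read_csv(path)
    expected = ["time_min", "concentration"]
    if list(df.columns[:2]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    t = df["time_min"].to_numpy(dtype=float)
    c = df["concentration"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least the t=0 sample plus one observation")
    if t[0] != 0:
        raise FormatError(f"{path}: first row must be t=0 (line 2)")
    diffs = np.diff(t)
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        raise FormatError(f"{path}: non-monotone or duplicate time at line {bad[0] + 3}")
    off_grid = np.flatnonzero(np.mod(t, dt) != 0)
    if off_grid.size:
        raise FormatError(f"{path}: time not on the {dt}-min grid at line {off_grid[0] + 2}")
    # re-index onto the full grid; absent rows become NaN and are interpolated
    grid = np.arange(0.0, t[-1] + dt, dt)
    s = pd.Series(c, index=t).reindex(grid)
    if np.isnan(s.iloc[0]) or np.isnan(s.iloc[-1]):
        raise FormatError(f"{path}: leading/trailing values must be present")
    s = s.interpolate(method="index", limit_area="inside")
    values = s.to_numpy()
    return CortisolSeries(y0=float(values[0]), values=values[1:], dt=dt, sigma_nu=sigma_nu)


def write_series(series: CortisolSeries, path) -> None:
    t = np.concatenate([[0.0], series.sample_times])
    v = np.concatenate([[series.y0], series.values])
    pd.DataFrame({"time_min": t, "concentration": v}).to_csv(path, index=False)


def read_pulses(path, n_grid: int = 1440) -> PulseTrain:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_min", "amplitude"]:
        raise FormatError(f"{path}: expected columns ['time_min', 'amplitude']")
    return PulseTrain(
        df["time_min"].to_numpy(dtype=int), df["amplitude"].to_numpy(dtype=float), n_grid=n_grid
    )


def write_pulses(pulses: PulseTrain, path) -> None:
    pd.DataFrame({"time_min": pulses.times, "amplitude": pulses.amplitudes}).to_csv(
        path, index=False
    )


def config_hash(cfg: Any) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _result_to_dict(result: DeconResult, config: Any = None) -> dict:
    return {
        "theta1": result.theta_hat.theta1,
        "theta2": result.theta_hat.theta2,
        "pulse_times": result.pulses_hat.times.tolist(),
        "pulse_amplitudes": result.pulses_hat.amplitudes.tolist(),
        "n_grid": result.pulses_hat.n_grid,
        "fitted": result.fitted.tolist(),
        "residuals": result.residuals.tolist(),
        "r_squared": None if np.isnan(result.r_squared) else result.r_squared,
        "final_lambda": result.final_lambda,
        "final_cost": result.final_cost,
        "n_pulses": result.n_pulses,
        "n_starts_used": result.n_starts_used,
        "seed": result.seed,
        "sparsity_in_band": result.sparsity_in_band,
        "config_hash": config_hash(config) if config is not None else None,
    }


def write_result(result: DeconResult, path, config: Any = None) -> None:
    Path(path).write_text(json.dumps(_result_to_dict(result, config), indent=1))


def read_result(path) -> DeconResult:
    d = json.loads(Path(path).read_text())
    return DeconResult(
        theta_hat=KineticParams(d["theta1"], d["theta2"]),
        pulses_hat=PulseTrain(
            np.asarray(d["pulse_times"], dtype=int),
            np.asarray(d["pulse_amplitudes"], dtype=float),
            n_grid=d["n_grid"],
        ),
        fitted=np.asarray(d["fitted"]),
        r_squared=np.nan if d["r_squared"] is None else d["r_squared"],
        final_lambda=d["final_lambda"],
        final_cost=d["final_cost"],
        residuals=np.asarray(d["residuals"]),
        n_pulses=d["n_pulses"],
        n_starts_used=d["n_starts_used"],
        seed=d["seed"],
        sparsity_in_band=d["sparsity_in_band"],
    )


def write_truth(theta: KineticParams, pulses: PulseTrain, path,
                seed: Optional[int] = None, sigma_nu: Optional[float] = None,
                y0: Optional[float] = None) -> None:
    Path(path).write_text(json.dumps({
        "theta1": theta.theta1,
        "theta2": theta.theta2,
        "pulse_times": pulses.times.tolist(),
        "pulse_amplitudes": pulses.amplitudes.tolist(),
        "n_grid": pulses.n_grid,
        "seed": seed,
        "sigma_nu": sigma_nu,
        "y0": y0,
    }, indent=1))


def read_truth(path) -> tuple[KineticParams, PulseTrain]:
    d = json.loads(Path(path).read_text())
    return (
        KineticParams(d["theta1"], d["theta2"]),
        PulseTrain(
            np.asarray(d["pulse_times"], dtype=int),
            np.asarray(d["pulse_amplitudes"], dtype=float),
            n_grid=d["n_grid"],
        ),
    )


def load_run_config(path) -> dict:
    """Load a YAML run configuration: solver/generator blocks plus n_starts, seed."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    out["solver"] = SparseSolverConfig(**raw.get("solver", {}))
    out["generator"] = PulseGenConfig(**{
        k: tuple(v) if k == "n_pulses_range" else v
        for k, v in raw.get("generator", {}).items()
    })
    out["n_starts"] = int(raw.get("n_starts", 10))
    out["seed"] = raw.get("seed")
    return out
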