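"""Fixed-step fourth-order Runge-Kutta integration of the normal forms.

Produces the theoretical outputs mu_i(theta): the ODE solution recorded at
M evenly spaced observation times.  Internal steps subdivide each
observation interval exactly, so observation times are hit without
interpolation.  A trajectory whose state exceeds the divergence threshold
(or becomes non-finite) on *any* internal step is flagged ``diverged`` —
all four drifts blow up in finite time once escaping, so the classification
is insensitive to the threshold over many orders of magnitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .models import ModelId, Theta

__all__ = [
    "TimeGrid",
    "SolverConfig",
    "Trajectory",
    "ConfigurationError",
    "integrate",
    "integrate_batch",
    "write_trajectory",
]

DEFAULT_T_END = 10.0
DEFAULT_STEP = 1e-3
DEFAULT_DIVERGENCE_THRESHOLD = 1e6


class ConfigurationError(ValueError):
    """Invalid time grid or solver settings (distinct from divergence)."""


@dataclass(frozen=True)
class TimeGrid:
    """M evenly spaced observation times spanning [t_start, t_end]."""

    n_obs: int
    t_start: float = 0.0
    t_end: float = DEFAULT_T_END

    def __post_init__(self) -> None:
        if not isinstance(self.n_obs, (int, np.integer)) or self.n_obs < 2:
            raise ConfigurationError(
                f"n_obs must be an integer >= 2, got {self.n_obs!r}"
            )
        if not (math.isfinite(self.t_start) and math.isfinite(self.t_end)):
            raise ConfigurationError("t_start and t_end must be finite")
        if self.t_end <= self.t_start:
            raise ConfigurationError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    @property
    def dt_obs(self) -> float:
        return (self.t_end - self.t_start) / (self.n_obs - 1)

    @property
    def obs_times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_obs)


@dataclass(frozen=True)
class SolverConfig:
    """RK4 internal step size and the absolute divergence bound."""

    step: float = DEFAULT_STEP
    divergence_threshold: float = DEFAULT_DIVERGENCE_THRESHOLD

    def __post_init__(self) -> None:
        if not (math.isfinite(self.step) and self.step > 0.0):
            raise ConfigurationError(f"step must be > 0, got {self.step!r}")
        if not (
            math.isfinite(self.divergence_threshold)
            and self.divergence_threshold > 0.0
        ):
            raise ConfigurationError(
                f"divergence_threshold must be > 0, got "
                f"{self.divergence_threshold!r}"
            )

    def n_sub(self, grid: TimeGrid) -> int:
        """Internal steps per observation interval (obs times hit exactly)."""
        if self.step > grid.dt_obs * (1.0 + 1e-12):
            raise ConfigurationError(
                f"step ({self.step}) exceeds observation spacing "
                f"({grid.dt_obs:.6g}); choose step <= spacing"
            )
        return max(1, math.ceil(grid.dt_obs / self.step - 1e-12))


@dataclass(frozen=True)
class Trajectory:
    """RK4 solution on a time grid, with divergence status.

    For a diverged run, ``times``/``states`` contain only the observation
    times strictly before ``divergence_time``.
    """

    times: np.ndarray
    states: np.ndarray
    status: str  # "ok" | "diverged"
    divergence_time: float | None = None
    model: ModelId | None = None
    theta: Theta | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def integrate(
    model: ModelId | str,
    theta: Theta,
    grid: TimeGrid,
    cfg: SolverConfig = SolverConfig(),
) -> Trajectory:
    """Classic RK4 with fixed step from theta.ic at t_start."""
    model = ModelId.from_name(model)
    n_sub = cfg.n_sub(grid)
    states, status, div_t = _kernels.rk4_single(
        model.code,
        float(theta.alpha),
        float(theta.ic),
        float(grid.t_start),
        float(grid.dt_obs),
        int(grid.n_obs),
        n_sub,
        float(cfg.divergence_threshold),
    )
    times = grid.obs_times
    if status == _kernels.OK:
        return Trajectory(times, states, "ok", None, model, theta)
    keep = times < div_t
    return Trajectory(
        times[keep], states[keep], "diverged", float(div_t), model, theta
    )


def integrate_batch(
    model: ModelId | str,
    alphas: np.ndarray,
    ics: np.ndarray,
    grid: TimeGrid,
    cfg: SolverConfig = SolverConfig(),
    max_chunk: int = 20_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised RK4 over many (alpha, ic) pairs on a shared grid.

    Returns ``(states, diverged, divergence_time)`` where ``states`` is
    (n, M) with NaN at and after divergence, ``diverged`` a boolean mask.
    Results are independent of chunking and evaluation order.
    """
    model = ModelId.from_name(model)
    alphas = np.ascontiguousarray(alphas, dtype=np.float64).ravel()
    ics = np.ascontiguousarray(ics, dtype=np.float64).ravel()
    if alphas.shape != ics.shape:
        raise ValueError("alphas and ics must have identical shapes")
    n_sub = cfg.n_sub(grid)
    n = alphas.size
    states = np.empty((n, grid.n_obs))
    status = np.empty(n, np.int8)
    div_time = np.empty(n)
    for lo in range(0, n, max_chunk):
        hi = min(lo + max_chunk, n)
        s, st, dt = _kernels.rk4_batch(
            model.code,
            alphas[lo:hi],
            ics[lo:hi],
            float(grid.t_start),
            float(grid.dt_obs),
            int(grid.n_obs),
            n_sub,
            float(cfg.divergence_threshold),
        )
        states[lo:hi] = s
        status[lo:hi] = st
        div_time[lo:hi] = dt
    return states, status == _kernels.DIVERGED, div_time


def write_trajectory(
    traj: Trajectory, csv_path: str | Path, cfg: SolverConfig | None = None
) -> None:
    """Export as CSV (time, state) with a JSON metadata sidecar."""
    import pandas as pd

    csv_path = Path(csv_path)
    pd.DataFrame({"time": traj.times, "state": traj.states}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    meta = {
        "model": traj.model.value if traj.model else None,
        "alpha": traj.theta.alpha if traj.theta else None,
        "ic": traj.theta.ic if traj.theta else None,
        "status": traj.status,
        "divergence_time": traj.divergence_time,
        "solver": {
            "step": cfg.step if cfg else None,
            "divergence_threshold": cfg.divergence_threshold if cfg else None,
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
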