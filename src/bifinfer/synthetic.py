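"""Synthetic observations: RK4 solutions plus i.i.d. Gaussian noise.

The study design: solve the ODE exactly (fixed-step RK4), sample it at M
evenly spaced time points, then add zero-mean Gaussian measurement noise
independently per time point *after* solving.  Named noise levels are
low (sigma = 0), moderate (sigma = 0.1) and heavy (sigma = 1.0); named
sampling densities are M = 1000 (very high), 500 (high) and 10 (low).

Every observation is reproducible from (model, theta_true, grid, noise,
seed): a single integer seed drives one dedicated ``numpy`` Generator per
observation.  Other noise models (e.g. log-normal) are a documented
extension point — subclass or wrap :func:`generate_observation` — but only
additive Gaussian noise is implemented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ModelId, Theta
from .simulate import SolverConfig, TimeGrid, integrate

__all__ = [
    "NOISE_LEVELS",
    "NoiseSpec",
    "Observation",
    "generate_observation",
    "sampling_presets",
    "write_observation",
    "read_observation",
]

#: The named noise levels (standard deviation of the Gaussian noise).
NOISE_LEVELS: dict[str, float] = {"low": 0.0, "moderate": 0.1, "heavy": 1.0}

#: The named sampling densities M, from very high to low.
SAMPLING_PRESETS: list[int] = [1000, 500, 10]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement-noise level sigma >= 0, optionally named."""

    sigma: float
    level_name: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma >= 0.0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")
        if self.level_name is not None:
            expected = NOISE_LEVELS.get(self.level_name)
            if expected is None:
                raise ValueError(
                    f"unknown noise level {self.level_name!r}; "
                    f"expected one of {sorted(NOISE_LEVELS)}"
                )
            if expected != self.sigma:
                raise ValueError(
                    f"level {self.level_name!r} means sigma = {expected}, "
                    f"got {self.sigma}"
                )

    @classmethod
    def from_level(cls, level_name: str) -> "NoiseSpec":
        if level_name not in NOISE_LEVELS:
            raise ValueError(
                f"unknown noise level {level_name!r}; "
                f"expected one of {sorted(NOISE_LEVELS)}"
            )
        return cls(sigma=NOISE_LEVELS[level_name], level_name=level_name)


@dataclass(frozen=True)
class Observation:
    """Synthetic data D = [y_1 ... y_M] with its generating settings.

    ``values`` is None when the generating theta diverges (``status ==
    "diverged"``); grid scans over divergent regions carry the flag
    instead of raising.
    """

    times: np.ndarray
    values: np.ndarray | None
    n_obs: int
    noise: NoiseSpec
    seed: int
    model: ModelId
    theta_true: Theta
    status: str  # "ok" | "diverged"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def sampling_presets() -> list[int]:
    """The study's sampling densities M: [1000, 500, 10]."""
    return list(SAMPLING_PRESETS)


def generate_observation(
    model: ModelId | str,
    theta_true: Theta,
    grid: TimeGrid,
    noise: NoiseSpec,
    seed: int,
    cfg: SolverConfig = SolverConfig(),
) -> Observation:
    """Solve the ODE at theta_true and add per-point Gaussian noise.

    With sigma = 0 the values equal the noiseless trajectory bit-exactly.
    The same (model, theta_true, grid, noise, seed) always reproduces the
    identical observation.
    """
    model = ModelId.from_name(model)
    traj = integrate(model, theta_true, grid, cfg)
    times = grid.obs_times
    if not traj.ok:
        return Observation(
            times=times,
            values=None,
            n_obs=grid.n_obs,
            noise=noise,
            seed=int(seed),
            model=model,
            theta_true=theta_true,
            status="diverged",
        )
    if noise.sigma == 0.0:
        values = traj.states.copy()
    else:
        rng = np.random.default_rng(int(seed))
        values = traj.states + noise.sigma * rng.standard_normal(grid.n_obs)
    return Observation(
        times=times,
        values=values,
        n_obs=grid.n_obs,
        noise=noise,
        seed=int(seed),
        model=model,
        theta_true=theta_true,
        status="ok",
    )


def write_observation(obs: Observation, csv_path: str | Path) -> None:
    """CSV (time, value) + JSON metadata; round-trips bit-exactly."""
    csv_path = Path(csv_path)
    values = obs.values if obs.values is not None else np.full(obs.n_obs, np.nan)
    df = pd.DataFrame({"time": obs.times, "value": values})
    # hex floats guarantee bit-exact round-tripping through text
    df["time"] = df["time"].map(float.hex)
    df["value"] = df["value"].map(float.hex)
    df.to_csv(csv_path, index=False)
    meta = {
        "model": obs.model.value,
        "alpha": obs.theta_true.alpha,
        "ic": obs.theta_true.ic,
        "sigma": obs.noise.sigma,
        "level_name": obs.noise.level_name,
        "M": obs.n_obs,
        "seed": obs.seed,
        "status": obs.status,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_observation(csv_path: str | Path) -> Observation:
    """Inverse of :func:`write_observation`."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    times = np.array([float.fromhex(v) for v in df["time"]])
    values = np.array([float.fromhex(v) for v in df["value"]])
    status = meta["status"]
    return Observation(
        times=times,
        values=None if status == "diverged" else values,
        n_obs=int(meta["M"]),
        noise=NoiseSpec(sigma=meta["sigma"], level_name=meta["level_name"]),
        seed=int(meta["seed"]),
        model=ModelId.from_name(meta["model"]),
        theta_true=Theta(meta["alpha"], meta["ic"]),
        status=status,
    )
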