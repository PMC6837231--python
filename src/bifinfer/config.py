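"""Run configuration: a flat, validated, serialisable experiment manifest.

A run is described by one plain YAML mapping with the flat keys below,
overridable by command-line flags (flags win).  Every completed run writes
its effective configuration back into its JSON metadata, so a run can be
reproduced bit-exactly from its own outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import ModelId, Theta
from .simulate import SolverConfig, TimeGrid
from .synthetic import NOISE_LEVELS, NoiseSpec

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value; names the offender."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with study defaults.

    alpha/ic are the true parameter pair for observation-based commands;
    the *_min/*_max/resolution keys define scan axes; sigma may be given
    directly or via level ("low"/"moderate"/"heavy").
    """

    model: str = "saddle_node"
    alpha: float = 1.0
    ic: float = 1.5
    sigma: float = 0.0
    level: str | None = None
    n_obs: int = 1000
    seed: int = 0
    t_start: float = 0.0
    t_end: float = 10.0
    step: float = 1e-3
    divergence_threshold: float = 1e6
    alpha_min: float = -2.0
    alpha_max: float = 2.0
    ic_min: float = -2.0
    ic_max: float = 2.0
    resolution: int = 101
    fd_step_alpha: float = 1e-3
    fd_step_ic: float = 1e-3
    fisher_mode: str = "trace"
    slice_ic: float = 1.5
    out_dir: str = "."

    _FLOATS = {
        "alpha", "ic", "sigma", "t_start", "t_end", "step",
        "divergence_threshold", "alpha_min", "alpha_max", "ic_min",
        "ic_max", "fd_step_alpha", "fd_step_ic", "slice_ic",
    }
    _INTS = {"n_obs", "seed", "resolution"}

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_sources(
        cls, config_path: str | Path | None = None, **overrides
    ) -> "RunConfig":
        """Build from an optional YAML file plus flag overrides (flags win)."""
        data: dict = {}
        if config_path is not None:
            loaded = yaml.safe_load(Path(config_path).read_text())
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a YAML mapping")
            data.update(loaded)
        for key, value in overrides.items():
            if value is not None:
                data[key] = value
        known = cls.field_names()
        for key in data:
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        ModelId.from_name(self.model)  # raises on unknown model
        for name in self._FLOATS:
            value = getattr(self, name)
            try:
                setattr(self, name, float(value))
            except (TypeError, ValueError):
                raise ConfigError(f"key {name!r} must be a number, got {value!r}")
        for name in self._INTS:
            value = getattr(self, name)
            if isinstance(value, bool) or not float(value).is_integer():
                raise ConfigError(f"key {name!r} must be an integer, got {value!r}")
            setattr(self, name, int(value))
        if self.level is not None:
            if self.level not in NOISE_LEVELS:
                raise ConfigError(
                    f"key 'level' must be one of {sorted(NOISE_LEVELS)}, "
                    f"got {self.level!r}"
                )
            self.sigma = NOISE_LEVELS[self.level]
        if self.sigma < 0:
            raise ConfigError(f"key 'sigma' must be >= 0, got {self.sigma}")
        if self.n_obs < 2:
            raise ConfigError(f"key 'n_obs' must be >= 2, got {self.n_obs}")
        if self.resolution < 2:
            raise ConfigError(f"key 'resolution' must be >= 2, got {self.resolution}")
        if self.t_end <= self.t_start:
            raise ConfigError("key 't_end' must exceed 't_start'")
        if self.step <= 0:
            raise ConfigError(f"key 'step' must be > 0, got {self.step}")
        if self.divergence_threshold <= 0:
            raise ConfigError("key 'divergence_threshold' must be > 0")
        if self.alpha_max <= self.alpha_min:
            raise ConfigError("key 'alpha_max' must exceed 'alpha_min'")
        if self.ic_max <= self.ic_min:
            raise ConfigError("key 'ic_max' must exceed 'ic_min'")
        if self.fd_step_alpha <= 0 or self.fd_step_ic <= 0:
            raise ConfigError("finite-difference steps must be > 0")
        if self.fisher_mode not in ("trace", "alpha_only"):
            raise ConfigError(
                f"key 'fisher_mode' must be 'trace' or 'alpha_only', "
                f"got {self.fisher_mode!r}"
            )

    # ---- derived objects ------------------------------------------------
    @property
    def model_id(self) -> ModelId:
        return ModelId.from_name(self.model)

    @property
    def theta_true(self) -> Theta:
        return Theta(self.alpha, self.ic)

    @property
    def time_grid(self) -> TimeGrid:
        return TimeGrid(n_obs=self.n_obs, t_start=self.t_start, t_end=self.t_end)

    @property
    def solver(self) -> SolverConfig:
        return SolverConfig(
            step=self.step, divergence_threshold=self.divergence_threshold
        )

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec(sigma=self.sigma, level_name=self.level)

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name) for f in dataclasses.fields(self)
        }
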