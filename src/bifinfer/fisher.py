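"""Observed Fisher information from finite-difference Hessians.

The observed Fisher information at theta is minus the Hessian of the
log-likelihood; we summarise it by its trace,

    FI_obs(theta) = -tr(Hessian(ln L(theta | D))) = -(H_aa + H_ii),

a scalar measure of how sharply the likelihood is curved around theta and
hence how reliably (alpha, IC) can be inferred there.  Whole-plane maps
evaluate each theta against its own noiseless simulation, so every grid
point is the exact MLE of its data and the curvature is the local
inferability of that parameter combination.

Second partials use central differences: 3-point stencils on the diagonal
and the 4-point cross stencil for the mixed term.  A stencil that touches
a divergent theta (including the centre itself) yields no Hessian; those
cells carry status ``divergent_set_zero`` with FI 0, matching the
convention of zeroing the map over divergent regions.  The affected margin
around a basin boundary is at most one finite-difference step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernels
from .inference import log_likelihood
from .models import ModelId, Theta
from .simulate import SolverConfig, TimeGrid, integrate_batch

__all__ = [
    "FDSteps",
    "HessianEstimate",
    "FisherValue",
    "FisherMap",
    "fd_hessian",
    "hessian_loglik",
    "fisher_trace",
    "fisher_map",
    "fisher_slice",
    "write_fisher_map",
]

DEFAULT_FD_STEP = 1e-3


@dataclass(frozen=True)
class FDSteps:
    """Central-difference steps in alpha and IC."""

    step_alpha: float = DEFAULT_FD_STEP
    step_ic: float = DEFAULT_FD_STEP

    def __post_init__(self) -> None:
        if self.step_alpha <= 0 or self.step_ic <= 0:
            raise ValueError("finite-difference steps must be > 0")


@dataclass(frozen=True)
class HessianEstimate:
    """Symmetric 2x2 Hessian of the log-likelihood (single mixed entry).

    ``valid`` is False when any of the 9 stencil evaluations hit -inf.
    """

    h_aa: float
    h_ai: float
    h_ii: float
    step_alpha: float
    step_ic: float
    valid: bool

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.h_aa, self.h_ai], [self.h_ai, self.h_ii]])


@dataclass(frozen=True)
class FisherValue:
    """Trace of the observed Fisher information at one theta."""

    trace_fi: float
    status: str  # "ok" | "divergent_set_zero"

    def __post_init__(self) -> None:
        if self.status == "divergent_set_zero" and self.trace_fi != 0.0:
            raise ValueError("divergent cells must carry FI exactly 0")


@dataclass(frozen=True)
class FisherMap:
    """FI trace over an (alpha, IC) grid; ``trace[i, j]`` at
    (alpha_axis[j], ic_axis[i]).  Raw traces are stored (tiny negative
    values from finite-difference error are preserved); ``clamped()``
    gives the plot-ready view with negatives floored at zero.
    """

    alpha_axis: np.ndarray
    ic_axis: np.ndarray
    trace: np.ndarray
    divergent: np.ndarray  # bool mask: status divergent_set_zero
    model: ModelId
    settings: dict

    def clamped(self) -> np.ndarray:
        return np.where(self.divergent, 0.0, np.maximum(self.trace, 0.0))

    def value_at(self, i: int, j: int) -> FisherValue:
        if self.divergent[i, j]:
            return FisherValue(0.0, "divergent_set_zero")
        return FisherValue(float(self.trace[i, j]), "ok")


# 9-point stencil offsets in units of (step_alpha, step_ic):
# centre, 4 axial points (diagonal second differences), 4 corners (mixed).
_STENCIL = np.array(
    [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)],
    dtype=np.float64,
)


def _hessian_from_stencil(ll: np.ndarray, ha: float, hi: float) -> tuple[float, float, float]:
    """ll ordered as _STENCIL: (c, +a, -a, +i, -i, ++, +-, -+, --)."""
    h_aa = (ll[1] + ll[2] - 2.0 * ll[0]) / (ha * ha)
    h_ii = (ll[3] + ll[4] - 2.0 * ll[0]) / (hi * hi)
    h_ai = (ll[5] - ll[6] - ll[7] + ll[8]) / (4.0 * ha * hi)
    return h_aa, h_ai, h_ii


def fd_hessian(
    fn: Callable[[float, float], float],
    alpha: float,
    ic: float,
    step_alpha: float = DEFAULT_FD_STEP,
    step_ic: float = DEFAULT_FD_STEP,
) -> HessianEstimate:
    """Central-difference Hessian of an arbitrary scalar field fn(alpha, ic).

    -inf function values invalidate the estimate rather than raising.
    """
    if step_alpha <= 0 or step_ic <= 0:
        raise ValueError("finite-difference steps must be > 0")
    ll = np.array(
        [fn(alpha + da * step_alpha, ic + di * step_ic) for da, di in _STENCIL]
    )
    if not np.all(np.isfinite(ll)):
        return HessianEstimate(np.nan, np.nan, np.nan, step_alpha, step_ic, False)
    h_aa, h_ai, h_ii = _hessian_from_stencil(ll, step_alpha, step_ic)
    return HessianEstimate(h_aa, h_ai, h_ii, step_alpha, step_ic, True)


def hessian_loglik(
    theta: Theta,
    obs,
    step_alpha: float = DEFAULT_FD_STEP,
    step_ic: float = DEFAULT_FD_STEP,
    grid: TimeGrid | None = None,
    cfg: SolverConfig = SolverConfig(),
) -> HessianEstimate:
    """FD Hessian of ln L(. | obs) at theta (works for noisy data too)."""
    if grid is None:
        grid = TimeGrid(
            n_obs=len(obs.times),
            t_start=float(obs.times[0]),
            t_end=float(obs.times[-1]),
        )

    def fn(a: float, ic: float) -> float:
        return log_likelihood(Theta(a, ic), obs, grid, cfg).value

    return fd_hessian(fn, theta.alpha, theta.ic, step_alpha, step_ic)


def _self_data_traces(
    model: ModelId,
    alphas: np.ndarray,
    ics: np.ndarray,
    grid: TimeGrid,
    cfg: SolverConfig,
    fd: FDSteps,
    mode: str = "trace",
) -> tuple[np.ndarray, np.ndarray]:
    """FI traces for many thetas, each against its own noiseless data.

    Returns (trace, divergent).  The centre log-likelihood is exactly 0
    (the data are the centre trajectory), so only the perturbed stencil
    points need evaluating.  ``mode`` "trace" uses the full 9-point
    stencil; "alpha_only" uses just the 3-point alpha stencil and reports
    -H_aa.
    """
    if mode not in ("trace", "alpha_only"):
        raise ValueError(f"mode must be 'trace' or 'alpha_only', got {mode!r}")
    n = alphas.size
    stencil = _STENCIL if mode == "trace" else _STENCIL[:3]
    k = len(stencil)
    all_a = (alphas[:, None] + stencil[:, 0] * fd.step_alpha).ravel()
    all_i = (ics[:, None] + stencil[:, 1] * fd.step_ic).ravel()
    states, diverged, _ = integrate_batch(model, all_a, all_i, grid, cfg)
    states = states.reshape(n, k, grid.n_obs)
    diverged = diverged.reshape(n, k)

    trace = np.zeros(n)
    bad = diverged.any(axis=1)
    ha, hi = fd.step_alpha, fd.step_ic
    for j in range(n):
        if bad[j]:
            continue
        y = states[j, 0]
        ll = np.empty(k)
        ll[0] = 0.0
        for s in range(1, k):
            ll[s] = _kernels.neg_half_sse(y, states[j, s])
        if not np.all(np.isfinite(ll)):
            bad[j] = True
            continue
        if mode == "trace":
            h_aa, _, h_ii = _hessian_from_stencil(ll, ha, hi)
            trace[j] = -(h_aa + h_ii)
        else:
            h_aa = (ll[1] + ll[2] - 2.0 * ll[0]) / (ha * ha)
            trace[j] = -h_aa
    trace[bad] = 0.0
    return trace, bad


def fisher_trace(
    model: ModelId | str,
    theta: Theta,
    grid: TimeGrid = TimeGrid(n_obs=1000),
    cfg: SolverConfig = SolverConfig(),
    fd_steps: FDSteps = FDSteps(),
    mode: str = "trace",
) -> FisherValue:
    """FI_obs at theta, evaluated against theta's own noiseless data.

    theta is then the exact MLE of the data it is scored on, which is the
    reading under which whole-plane maps are well defined.  Returns
    (0, "divergent_set_zero") if theta or any stencil neighbour diverges.
    """
    model = ModelId.from_name(model)
    trace, bad = _self_data_traces(
        model,
        np.array([theta.alpha]),
        np.array([theta.ic]),
        grid,
        cfg,
        fd_steps,
        mode,
    )
    if bad[0]:
        return FisherValue(0.0, "divergent_set_zero")
    return FisherValue(float(trace[0]), "ok")


def _settings_dict(grid: TimeGrid, cfg: SolverConfig, fd: FDSteps, mode: str) -> dict:
    return {
        "t_start": grid.t_start,
        "t_end": grid.t_end,
        "n_obs": grid.n_obs,
        "solver_step": cfg.step,
        "divergence_threshold": cfg.divergence_threshold,
        "fd_step_alpha": fd.step_alpha,
        "fd_step_ic": fd.step_ic,
        "mode": mode,
    }


def fisher_map(
    model: ModelId | str,
    alpha_axis: np.ndarray,
    ic_axis: np.ndarray,
    grid: TimeGrid = TimeGrid(n_obs=1000),
    cfg: SolverConfig = SolverConfig(),
    fd_steps: FDSteps = FDSteps(),
    mode: str = "trace",
) -> FisherMap:
    """FI trace at every cell of an (alpha, IC) grid.

    Cells are independent (embarrassingly parallel contract): the result
    does not depend on evaluation order.
    """
    model = ModelId.from_name(model)
    alpha_axis = np.asarray(alpha_axis, dtype=np.float64)
    ic_axis = np.asarray(ic_axis, dtype=np.float64)
    for name, ax in (("alpha_axis", alpha_axis), ("ic_axis", ic_axis)):
        if ax.size == 0 or (ax.size > 1 and not np.all(np.diff(ax) > 0)):
            raise ValueError(f"{name} must be non-empty and strictly increasing")
    aa, ii = np.meshgrid(alpha_axis, ic_axis)
    trace, bad = _self_data_traces(
        model, aa.ravel(), ii.ravel(), grid, cfg, fd_steps, mode
    )
    shape = (len(ic_axis), len(alpha_axis))
    return FisherMap(
        alpha_axis=alpha_axis,
        ic_axis=ic_axis,
        trace=trace.reshape(shape),
        divergent=bad.reshape(shape),
        model=model,
        settings=_settings_dict(grid, cfg, fd_steps, mode),
    )


def default_map_axes(resolution: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """The default map extent: alpha, IC in [-2, 2]."""
    return np.linspace(-2, 2, resolution), np.linspace(-2, 2, resolution)


def fisher_slice(
    model: ModelId | str,
    ic: float,
    alpha_axis: np.ndarray,
    grid: TimeGrid = TimeGrid(n_obs=1000),
    cfg: SolverConfig = SolverConfig(),
    fd_steps: FDSteps = FDSteps(),
    mode: str = "trace",
) -> list[tuple[float, FisherValue]]:
    """Marginal FI along alpha at fixed IC: one row of the map.

    By default each value is the full 2x2-trace FI (the IC = const row of
    the trace map); ``mode="alpha_only"`` instead reports the pure alpha
    curvature -H_aa.
    """
    model = ModelId.from_name(model)
    alpha_axis = np.asarray(alpha_axis, dtype=np.float64)
    if alpha_axis.size == 0 or (
        alpha_axis.size > 1 and not np.all(np.diff(alpha_axis) > 0)
    ):
        raise ValueError("alpha_axis must be non-empty and strictly increasing")
    trace, bad = _self_data_traces(
        model,
        alpha_axis,
        np.full(alpha_axis.size, float(ic)),
        grid,
        cfg,
        fd_steps,
        mode,
    )
    out = []
    for j, a in enumerate(alpha_axis):
        fv = (
            FisherValue(0.0, "divergent_set_zero")
            if bad[j]
            else FisherValue(float(trace[j]), "ok")
        )
        out.append((float(a), fv))
    return out


def write_fisher_map(fmap: FisherMap, csv_path: str | Path, clamp: bool = True) -> None:
    """Long-format CSV (alpha, ic, fi, status) + JSON settings sidecar."""
    csv_path = Path(csv_path)
    aa, ii = np.meshgrid(fmap.alpha_axis, fmap.ic_axis)
    fi = fmap.clamped() if clamp else fmap.trace
    status = np.where(fmap.divergent, "divergent_set_zero", "ok")
    pd.DataFrame(
        {
            "alpha": aa.ravel(),
            "ic": ii.ravel(),
            "fi": fi.ravel(),
            "status": status.ravel(),
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "model": fmap.model.value,
        "clamped": clamp,
        "alpha_min": float(fmap.alpha_axis[0]),
        "alpha_max": float(fmap.alpha_axis[-1]),
        "ic_min": float(fmap.ic_axis[0]),
        "ic_max": float(fmap.ic_axis[-1]),
        "n_alpha": len(fmap.alpha_axis),
        "n_ic": len(fmap.ic_axis),
        **fmap.settings,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
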