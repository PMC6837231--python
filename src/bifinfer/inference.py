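"""Log-likelihood, likelihood surfaces over the (alpha, IC) plane, and MLE.

Under i.i.d. Gaussian measurement noise the log-likelihood of theta given
observations D = [y_1 ... y_M] is, up to a constant,

    ln L(theta | D) = -1/2 * sum_i (y_i - mu_i(theta))^2

where mu_i(theta) is the RK4 solution at observation time t_i.  The
proportionality constant is fixed to 0 and no 1/sigma^2 weighting is
applied; neither changes the location of the maximum.  A theta whose
trajectory diverges inside the observation window has no defined
likelihood and is assigned -inf: divergent regions of the plane are
explicitly non-inferable rather than merely penalised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import _kernels
from .models import ModelId, Theta
from .simulate import SolverConfig, TimeGrid, integrate_batch

__all__ = [
    "LogLikValue",
    "SurfaceResult",
    "MleResult",
    "NoFiniteLikelihoodError",
    "log_likelihood",
    "likelihood_surface",
    "find_mle",
    "write_surface",
]

COARSE_GRID_SIZE = 41


class NoFiniteLikelihoodError(RuntimeError):
    """Every probed theta diverges: the likelihood is nowhere defined."""


@dataclass(frozen=True)
class LogLikValue:
    """A log-likelihood value; -inf (with the flag) marks divergence."""

    value: float
    diverged: bool = False

    def __post_init__(self) -> None:
        if self.diverged != (self.value == -np.inf):
            raise ValueError("diverged must hold exactly when value is -inf")


@dataclass(frozen=True)
class SurfaceResult:
    """Log-likelihood over an (alpha, IC) grid.

    ``loglik[i, j]`` is the value at (alpha_axis[j], ic_axis[i]); -inf
    entries (mask in ``diverged``) mark divergent cells.  ``argmax`` is the
    grid cell with the maximal finite value, ties broken by smallest alpha
    then smallest IC.
    """

    alpha_axis: np.ndarray
    ic_axis: np.ndarray
    loglik: np.ndarray
    diverged: np.ndarray
    argmax: Theta


@dataclass(frozen=True)
class MleResult:
    theta_hat: Theta
    loglik_at_hat: LogLikValue
    n_evaluations: int


def _grid_from_times(times: np.ndarray) -> TimeGrid:
    return TimeGrid(n_obs=len(times), t_start=float(times[0]), t_end=float(times[-1]))


def _check_obs(obs, grid: TimeGrid) -> None:
    if not obs.ok:
        raise ValueError("observation has diverged status; no data to fit")
    if len(obs.times) != grid.n_obs or not np.array_equal(obs.times, grid.obs_times):
        raise ValueError("observation times do not match the time grid")


def log_likelihood(
    theta: Theta,
    obs,
    grid: TimeGrid,
    cfg: SolverConfig = SolverConfig(),
) -> LogLikValue:
    """ln L(theta | D) = -1/2 * sum (y_i - mu_i(theta))^2, or -inf."""
    _check_obs(obs, grid)
    values = _loglik_batch(
        obs.model if hasattr(obs, "model") else None,
        np.array([theta.alpha]),
        np.array([theta.ic]),
        obs,
        grid,
        cfg,
    )[0]
    return LogLikValue(value=float(values), diverged=not np.isfinite(values))


def _loglik_batch(model, alphas, ics, obs, grid, cfg) -> np.ndarray:
    """Vectorised log-likelihood; -inf where the trajectory diverges."""
    model = ModelId.from_name(model if model is not None else obs.model)
    states, diverged, _ = integrate_batch(model, alphas, ics, grid, cfg)
    y = np.asarray(obs.values, dtype=np.float64)
    out = np.empty(alphas.size)
    for j in range(alphas.size):
        out[j] = -np.inf if diverged[j] else _kernels.neg_half_sse(y, states[j])
    return out


def _tie_broken_argmax(
    loglik: np.ndarray, alpha_axis: np.ndarray, ic_axis: np.ndarray
) -> Theta:
    finite = np.isfinite(loglik)
    if not finite.any():
        raise NoFiniteLikelihoodError(
            "log-likelihood is -inf on the entire grid (all thetas diverge)"
        )
    best = loglik[finite].max()
    rows, cols = np.nonzero((loglik == best) & finite)
    # smallest alpha first, then smallest IC
    order = np.lexsort((ic_axis[rows], alpha_axis[cols]))
    i = order[0]
    return Theta(float(alpha_axis[cols[i]]), float(ic_axis[rows[i]]))


def likelihood_surface(
    model: ModelId | str,
    obs,
    alpha_axis: np.ndarray,
    ic_axis: np.ndarray,
    grid: TimeGrid | None = None,
    cfg: SolverConfig = SolverConfig(),
) -> SurfaceResult:
    """Evaluate the log-likelihood at every (alpha, IC) grid cell."""
    model = ModelId.from_name(model)
    alpha_axis = np.asarray(alpha_axis, dtype=np.float64)
    ic_axis = np.asarray(ic_axis, dtype=np.float64)
    for name, ax in (("alpha_axis", alpha_axis), ("ic_axis", ic_axis)):
        if ax.size == 0 or (ax.size > 1 and not np.all(np.diff(ax) > 0)):
            raise ValueError(f"{name} must be non-empty and strictly increasing")
    if grid is None:
        grid = _grid_from_times(obs.times)
    _check_obs(obs, grid)
    aa, ii = np.meshgrid(alpha_axis, ic_axis)
    flat = _loglik_batch(model, aa.ravel(), ii.ravel(), obs, grid, cfg)
    loglik = flat.reshape(len(ic_axis), len(alpha_axis))
    argmax = _tie_broken_argmax(loglik, alpha_axis, ic_axis)
    return SurfaceResult(
        alpha_axis=alpha_axis,
        ic_axis=ic_axis,
        loglik=loglik,
        diverged=~np.isfinite(loglik),
        argmax=argmax,
    )


def find_mle(
    model: ModelId | str,
    obs,
    alpha_bounds: tuple[float, float],
    ic_bounds: tuple[float, float],
    cfg: SolverConfig = SolverConfig(),
    coarse: int = COARSE_GRID_SIZE,
) -> MleResult:
    """Coarse grid search then derivative-free (Nelder-Mead) refinement.

    The coarse stage is a ``coarse`` x ``coarse`` grid over the bounds;
    refinement starts from the best cell, uses only function evaluations,
    and never leaves the bounds.  Deterministic for fixed inputs.
    """
    model = ModelId.from_name(model)
    for name, (lo, hi) in (("alpha_bounds", alpha_bounds), ("ic_bounds", ic_bounds)):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{name} must be finite with lower < upper")
    grid = _grid_from_times(obs.times)
    _check_obs(obs, grid)

    alpha_axis = np.linspace(alpha_bounds[0], alpha_bounds[1], coarse)
    ic_axis = np.linspace(ic_bounds[0], ic_bounds[1], coarse)
    aa, ii = np.meshgrid(alpha_axis, ic_axis)
    flat = _loglik_batch(model, aa.ravel(), ii.ravel(), obs, grid, cfg)
    loglik = flat.reshape(coarse, coarse)
    start = _tie_broken_argmax(loglik, alpha_axis, ic_axis)
    n_evals = coarse * coarse

    y = np.asarray(obs.values, dtype=np.float64)
    n_sub = cfg.n_sub(grid)

    def neg_ll(p: np.ndarray) -> float:
        a, ic = float(p[0]), float(p[1])
        if not (alpha_bounds[0] <= a <= alpha_bounds[1]) or not (
            ic_bounds[0] <= ic <= ic_bounds[1]
        ):
            return np.inf
        mu, status, _ = _kernels.rk4_single(
            model.code, a, ic, float(grid.t_start), float(grid.dt_obs),
            int(grid.n_obs), n_sub, float(cfg.divergence_threshold),
        )
        if status != _kernels.OK:
            return np.inf
        return -_kernels.neg_half_sse(y, mu)

    res = optimize.minimize(
        neg_ll,
        x0=np.array([start.alpha, start.ic]),
        method="Nelder-Mead",
        bounds=[alpha_bounds, ic_bounds],
        options={"xatol": 1e-6, "fatol": 1e-10, "maxfev": 400},
    )
    n_evals += int(res.nfev)
    cand = Theta(float(res.x[0]), float(res.x[1]))
    cand_ll = -float(res.fun)
    start_ll = float(loglik[np.nonzero(ic_axis == start.ic)[0][0],
                            np.nonzero(alpha_axis == start.alpha)[0][0]])
    # refinement never makes things worse than the coarse optimum
    if not np.isfinite(cand_ll) or cand_ll < start_ll:
        cand, cand_ll = start, start_ll
    return MleResult(
        theta_hat=cand,
        loglik_at_hat=LogLikValue(value=cand_ll, diverged=not np.isfinite(cand_ll)),
        n_evaluations=n_evals,
    )


def write_surface(surface: SurfaceResult, csv_path: str | Path, meta: dict | None = None) -> None:
    """Long-format CSV (alpha, ic, loglik, diverged) + JSON metadata."""
    csv_path = Path(csv_path)
    aa, ii = np.meshgrid(surface.alpha_axis, surface.ic_axis)
    pd.DataFrame(
        {
            "alpha": aa.ravel(),
            "ic": ii.ravel(),
            "loglik": surface.loglik.ravel(),
            "diverged": surface.diverged.ravel(),
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "argmax_alpha": surface.argmax.alpha,
        "argmax_ic": surface.argmax.ic,
        **(meta or {}),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
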