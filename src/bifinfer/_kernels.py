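"""Compiled fixed-step RK4 kernels.

The whole-plane Fisher maps and likelihood surfaces evaluate tens of
thousands of trajectories, each with ~1e4 internal steps, so the classic
RK4 loop lives in a numba-jitted kernel.  Divergence (|X| beyond a bound,
or a non-finite state) is checked after every *internal* step, not just at
observation times, so blow-up between sparse observations is still caught.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes
OK = 0
DIVERGED = 1


@njit(cache=False)
def _f(code: int, x: float, a: float) -> float:
    if code == 0:  # saddle-node
        return a - x * x
    if code == 1:  # transcritical
        return a * x - x * x
    if code == 2:  # supercritical pitchfork
        return a * x - x * x * x
    return a * x + x * x * x  # subcritical pitchfork


@njit(cache=False)
def rk4_single(code, alpha, ic, t_start, dt_obs, n_obs, n_sub, threshold):
    """Integrate one trajectory; returns (states, status, divergence_time).

    ``states[i]`` is X at observation time t_start + i*dt_obs; entries at
    and after the divergence time are NaN.
    """
    states = np.full(n_obs, np.nan)
    h = dt_obs / n_sub
    x = ic
    t = t_start
    if not np.isfinite(x) or abs(x) > threshold:
        return states, DIVERGED, t
    states[0] = x
    for i in range(1, n_obs):
        for k in range(n_sub):
            k1 = _f(code, x, alpha)
            k2 = _f(code, x + 0.5 * h * k1, alpha)
            k3 = _f(code, x + 0.5 * h * k2, alpha)
            k4 = _f(code, x + h * k3, alpha)
            x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t = t_start + ((i - 1) * n_sub + k + 1) * h
            if not np.isfinite(x) or abs(x) > threshold:
                return states, DIVERGED, t
        states[i] = x
    return states, OK, np.nan


@njit(cache=False)
def rk4_batch(code, alphas, ics, t_start, dt_obs, n_obs, n_sub, threshold):
    """Integrate a batch of (alpha, ic) pairs on a shared time grid."""
    n = alphas.shape[0]
    states = np.empty((n, n_obs))
    status = np.empty(n, np.int8)
    div_time = np.empty(n)
    for j in range(n):
        s, st, dt = rk4_single(
            code, alphas[j], ics[j], t_start, dt_obs, n_obs, n_sub, threshold
        )
        states[j] = s
        status[j] = st
        div_time[j] = dt
    return states, status, div_time


@njit(cache=False)
def neg_half_sse(y, mu):
    """-0.5 * sum of squared residuals; -inf if mu has any NaN."""
    total = 0.0
    for i in range(y.shape[0]):
        if not np.isfinite(mu[i]):
            return -np.inf
        d = y[i] - mu[i]
        total += d * d
    return -0.5 * total
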