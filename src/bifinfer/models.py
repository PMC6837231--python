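"""The four scalar co-dimension 1 bifurcation normal forms.

Each model is a one-dimensional ODE dX/dt = f(X; alpha) in which varying the
single bifurcation parameter ``alpha`` through 0 changes the number or the
stability of the equilibria:

=========================  =====================
saddle_node                f = alpha - X^2
transcritical              f = alpha*X - X^2
pitchfork_supercritical    f = alpha*X - X^3
pitchfork_subcritical      f = alpha*X + X^3
=========================  =====================

This module provides the drift fields, analytic fixed points with stability
labels from the linearisation, and exact closed-form solutions of all four
ODEs (every one is a Bernoulli equation, or tanh/tan-solvable in the
saddle-node case).  The closed forms serve as independent oracles for the
numerical integrator and report finite-time blow-up exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ModelId",
    "Theta",
    "FixedPoint",
    "FixedPointSet",
    "BlowUpError",
    "drift",
    "drift_dx",
    "fixed_points",
    "closed_form_solution",
    "blow_up_time",
]

#: |f'(X*)| below this is classified *marginal* (the exact bifurcation
#: points, e.g. alpha = 0) rather than stable/unstable.
STABILITY_TOL = 1e-10


class ModelId(str, Enum):
    """One of the four co-dimension 1 normal forms."""

    SADDLE_NODE = "saddle_node"
    TRANSCRITICAL = "transcritical"
    PITCHFORK_SUPERCRITICAL = "pitchfork_supercritical"
    PITCHFORK_SUBCRITICAL = "pitchfork_subcritical"

    @classmethod
    def from_name(cls, name: "str | ModelId") -> "ModelId":
        if isinstance(name, ModelId):
            return name
        try:
            return cls(name)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown model {name!r}; expected one of: {valid}"
            ) from None

    @property
    def code(self) -> int:
        """Integer code used by the compiled integrator kernel."""
        return _MODEL_CODES[self]


_MODEL_CODES = {
    ModelId.SADDLE_NODE: 0,
    ModelId.TRANSCRITICAL: 1,
    ModelId.PITCHFORK_SUPERCRITICAL: 2,
    ModelId.PITCHFORK_SUBCRITICAL: 3,
}


@dataclass(frozen=True)
class Theta:
    """The inferred parameter pair theta = (alpha, IC).

    ``alpha`` is the bifurcation parameter of the normal form and ``ic`` the
    initial condition X(0); the two are inferred jointly.
    """

    alpha: float
    ic: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.ic)):
            raise ValueError(f"theta components must be finite, got {self}")


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium X* with its linear stability label."""

    location: float
    stability: str  # "stable" | "unstable" | "marginal"


@dataclass(frozen=True)
class FixedPointSet:
    """All real equilibria of a normal form at one alpha, ascending in X."""

    alpha: float
    points: tuple[FixedPoint, ...]

    @property
    def count(self) -> int:
        return len(self.points)

    def locations(self) -> list[float]:
        return [p.location for p in self.points]


class BlowUpError(RuntimeError):
    """A trajectory reaches infinity in finite time before the query time."""

    def __init__(self, blow_up_time: float):
        super().__init__(f"solution blows up at t = {blow_up_time:.6g}")
        self.blow_up_time = blow_up_time


def _check_finite(**kwargs) -> None:
    import numpy as np

    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


def drift(model: ModelId | str, x, alpha: float):
    """Evaluate the drift f(X; alpha); ``x`` may be a scalar or an array."""
    model = ModelId.from_name(model)
    _check_finite(x=x, alpha=alpha)
    if model is ModelId.SADDLE_NODE:
        return alpha - x * x
    if model is ModelId.TRANSCRITICAL:
        return alpha * x - x * x
    if model is ModelId.PITCHFORK_SUPERCRITICAL:
        return alpha * x - x ** 3
    return alpha * x + x ** 3


def drift_dx(model: ModelId | str, x, alpha: float):
    """State derivative of the drift, used for linear stability."""
    model = ModelId.from_name(model)
    _check_finite(x=x, alpha=alpha)
    if model is ModelId.SADDLE_NODE:
        return -2.0 * x
    if model is ModelId.TRANSCRITICAL:
        return alpha - 2.0 * x
    if model is ModelId.PITCHFORK_SUPERCRITICAL:
        return alpha - 3.0 * x * x
    return alpha + 3.0 * x * x


def _classify(model: ModelId, x: float, alpha: float) -> FixedPoint:
    slope = drift_dx(model, x, alpha)
    if slope < -STABILITY_TOL:
        stability = "stable"
    elif slope > STABILITY_TOL:
        stability = "unstable"
    else:
        stability = "marginal"
    return FixedPoint(location=x, stability=stability)


def fixed_points(model: ModelId | str, alpha: float) -> FixedPointSet:
    """All real equilibria of the model at this alpha, with stability.

    Roots are taken analytically (the drifts are fixed quadratics/cubics):

    * saddle-node: none for alpha < 0, the marginal double root 0 at
      alpha = 0, and +-sqrt(alpha) for alpha > 0;
    * transcritical: 0 and alpha (coincident, marginal, at alpha = 0) —
      they exchange stability as alpha crosses 0;
    * supercritical pitchfork: 0 always, plus +-sqrt(alpha) for alpha > 0;
    * subcritical pitchfork: 0 always, plus +-sqrt(-alpha) for alpha < 0.
    """
    model = ModelId.from_name(model)
    _check_finite(alpha=alpha)
    roots: list[float]
    if model is ModelId.SADDLE_NODE:
        if alpha < 0.0:
            roots = []
        elif alpha == 0.0:
            roots = [0.0]
        else:
            r = math.sqrt(alpha)
            roots = [-r, r]
    elif model is ModelId.TRANSCRITICAL:
        roots = [0.0] if alpha == 0.0 else sorted({0.0, alpha})
    elif model is ModelId.PITCHFORK_SUPERCRITICAL:
        if alpha > 0.0:
            r = math.sqrt(alpha)
            roots = [-r, 0.0, r]
        else:
            roots = [0.0]
    else:  # subcritical pitchfork
        if alpha < 0.0:
            r = math.sqrt(-alpha)
            roots = [-r, 0.0, r]
        else:
            roots = [0.0]
    points = tuple(_classify(model, x, alpha) for x in sorted(roots))
    return FixedPointSet(alpha=alpha, points=points)


# ---------------------------------------------------------------------------
# Closed-form solutions (integrator oracles)
#
# Saddle-node, dX/dt = alpha - X^2:
#   alpha > 0, s = sqrt(alpha):
#       X(t) = s (X0 + s tanh(s t)) / (s + X0 tanh(s t))
#     blows up iff X0 < -s, when tanh(s t*) = -s/X0.
#   alpha = 0: X(t) = X0 / (1 + X0 t); blows up iff X0 < 0 at t* = -1/X0.
#   alpha < 0, b = sqrt(-alpha):
#       X(t) = b tan(arctan(X0/b) - b t)
#     always blows up, at t* = (arctan(X0/b) + pi/2) / b.
#
# Transcritical, dX/dt = alpha X - X^2 (logistic; Bernoulli via u = 1/X):
#   alpha != 0: X(t) = alpha X0 / (X0 + (alpha - X0) e^{-alpha t});
#     blows up when the denominator crosses 0, i.e. when
#     e^{alpha t*} = (X0 - alpha)/X0 with that ratio in the reachable range.
#   alpha = 0: reduces to dX/dt = -X^2, same as the saddle-node alpha = 0.
#
# Pitchforks, dX/dt = alpha X -+ X^3 (Bernoulli via u = X^{-2}):
#   supercritical: u' = -2 alpha u + 2, u stays positive, never blows up:
#       alpha != 0: u(t) = 1/alpha + (u0 - 1/alpha) e^{-2 alpha t}
#       alpha  = 0: u(t) = u0 + 2 t
#   subcritical:   u' = -2 alpha u - 2, blows up when u(t) hits 0:
#       alpha != 0: u(t) = -1/alpha + (u0 + 1/alpha) e^{-2 alpha t}
#       alpha  = 0: u(t) = u0 - 2 t
#   and X(t) = sign(X0) / sqrt(u(t)), X identically 0 for X0 = 0.
# ---------------------------------------------------------------------------


def blow_up_time(model: ModelId | str, theta: Theta) -> float:
    """Exact finite blow-up time of the solution, or ``inf`` if global.

    Derived from the closed forms above; used both by
    :func:`closed_form_solution` and as an oracle for divergence detection.
    """
    model = ModelId.from_name(model)
    a, x0 = theta.alpha, theta.ic

    if model is ModelId.SADDLE_NODE:
        if a > 0.0:
            s = math.sqrt(a)
            if x0 < -s:
                return math.atanh(-s / x0) / s
            return math.inf
        if a == 0.0:
            return -1.0 / x0 if x0 < 0.0 else math.inf
        b = math.sqrt(-a)
        return (math.atan(x0 / b) + math.pi / 2.0) / b

    if model is ModelId.TRANSCRITICAL:
        if a == 0.0:
            return -1.0 / x0 if x0 < 0.0 else math.inf
        if x0 == 0.0:
            return math.inf
        ratio = (x0 - a) / x0
        if a > 0.0:
            # e^{alpha t} grows from 1; reachable iff ratio > 1 (X0 < 0).
            return math.log(ratio) / a if ratio > 1.0 else math.inf
        # alpha < 0: e^{alpha t} decays from 1; reachable iff 0 < ratio < 1.
        return math.log(ratio) / a if 0.0 < ratio < 1.0 else math.inf

    if model is ModelId.PITCHFORK_SUPERCRITICAL:
        return math.inf

    # subcritical pitchfork
    if x0 == 0.0:
        return math.inf
    u0 = 1.0 / (x0 * x0)
    if a == 0.0:
        return u0 / 2.0
    if a > 0.0:
        return math.log(1.0 + a * u0) / (2.0 * a)
    # alpha < 0: inside the basin |X0| < sqrt(-alpha) the state decays to 0.
    if u0 >= -1.0 / a:  # X0^2 <= -alpha
        return math.inf
    return math.log(1.0 / (1.0 + a * u0)) / (-2.0 * a)


def closed_form_solution(model: ModelId | str, theta: Theta, t: float) -> float:
    """Exact solution X(t) of the normal-form ODE started at theta.ic.

    Raises :class:`BlowUpError` if the solution reaches infinity at or
    before ``t``.  See the module source for the derivation of each branch.
    """
    model = ModelId.from_name(model)
    if not math.isfinite(t) or t < 0.0:
        raise ValueError(f"t must be finite and >= 0, got {t!r}")
    a, x0 = theta.alpha, theta.ic

    t_star = blow_up_time(model, theta)
    if t >= t_star:
        raise BlowUpError(t_star)

    if model is ModelId.SADDLE_NODE:
        if a > 0.0:
            s = math.sqrt(a)
            th = math.tanh(s * t)
            return s * (x0 + s * th) / (s + x0 * th)
        if a == 0.0:
            return x0 / (1.0 + x0 * t)
        b = math.sqrt(-a)
        return b * math.tan(math.atan(x0 / b) - b * t)

    if model is ModelId.TRANSCRITICAL:
        if a == 0.0:
            return x0 / (1.0 + x0 * t)
        if x0 == 0.0:
            return 0.0
        return a * x0 / (x0 + (a - x0) * math.exp(-a * t))

    # both pitchforks via u = X^{-2}
    if x0 == 0.0:
        return 0.0
    u0 = 1.0 / (x0 * x0)
    sign = 1.0 if x0 > 0.0 else -1.0
    if model is ModelId.PITCHFORK_SUPERCRITICAL:
        if a == 0.0:
            u = u0 + 2.0 * t
        else:
            u = 1.0 / a + (u0 - 1.0 / a) * math.exp(-2.0 * a * t)
    else:
        if a == 0.0:
            u = u0 - 2.0 * t
        else:
            u = -1.0 / a + (u0 + 1.0 / a) * math.exp(-2.0 * a * t)
    return sign / math.sqrt(u)
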