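"""Normal forms: drifts, analytic fixed points, closed-form solutions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bifinfer import (
    BlowUpError,
    ModelId,
    Theta,
    TimeGrid,
    SolverConfig,
    blow_up_time,
    closed_form_solution,
    drift,
    drift_dx,
    fixed_points,
    integrate,
)

from conftest import ALL_MODELS


@pytest.mark.parametrize(
    "model,x,alpha,expected",
    [
        ("saddle_node", 0.0, 1.0, 1.0),
        ("transcritical", 0.0, 7.0, 0.0),
        ("pitchfork_subcritical", 2.0, 1.0, 10.0),
        ("pitchfork_supercritical", 2.0, 1.0, -6.0),
    ],
)
def test_drift_direct_substitution(model, x, alpha, expected):
    assert drift(model, x, alpha) == expected


def test_drift_rejects_non_finite():
    with pytest.raises(ValueError):
        drift("saddle_node", float("nan"), 1.0)
    with pytest.raises(ValueError):
        drift("saddle_node", 0.0, float("inf"))


def test_unknown_model_rejected():
    with pytest.raises(ValueError, match="unknown model"):
        drift("hopf", 0.0, 1.0)
    assert len(list(ModelId)) == 4


@pytest.mark.parametrize(
    "model,alpha,expected",
    [
        ("saddle_node", -1.0, []),
        ("saddle_node", 0.0, [(0.0, "marginal")]),
        ("saddle_node", 4.0, [(-2.0, "unstable"), (2.0, "stable")]),
        ("transcritical", 1.0, [(0.0, "unstable"), (1.0, "stable")]),
        ("transcritical", -1.0, [(-1.0, "unstable"), (0.0, "stable")]),
        ("pitchfork_supercritical", -1.0, [(0.0, "stable")]),
        (
            "pitchfork_supercritical",
            1.0,
            [(-1.0, "stable"), (0.0, "unstable"), (1.0, "stable")],
        ),
        (
            "pitchfork_subcritical",
            -1.0,
            [(-1.0, "unstable"), (0.0, "stable"), (1.0, "unstable")],
        ),
    ],
)
def test_fixed_point_enumeration(model, alpha, expected):
    fps = fixed_points(model, alpha)
    assert [(p.location, p.stability) for p in fps.points] == expected


def _brute_force_root_count(model, alpha):
    """Sign-change scan of the drift on X in [-10, 10] at resolution 1e-4."""
    x = np.linspace(-10.0, 10.0, 200_001)
    if model == "saddle_node":
        f = alpha - x**2
    elif model == "transcritical":
        f = alpha * x - x**2
    elif model == "pitchfork_supercritical":
        f = alpha * x - x**3
    else:
        f = alpha * x + x**3
    zero = np.abs(f) < 1e-9
    count = 0
    in_zero_run = False
    for i in range(len(x)):
        if zero[i]:
            if not in_zero_run:
                count += 1
                in_zero_run = True
        else:
            in_zero_run = False
            if i + 1 < len(x) and not zero[i + 1] and f[i] * f[i + 1] < 0:
                count += 1
    return count


def test_fixed_points_match_brute_force_scan():
    """Analytic roots agree with a sign-change scan for 200 random alphas."""
    rng = np.random.default_rng(42)
    alphas = rng.uniform(-2.0, 2.0, 200)
    for model in ALL_MODELS:
        for alpha in alphas:
            fps = fixed_points(model, float(alpha))
            for p in fps.points:
                assert abs(drift(model, p.location, float(alpha))) < 1e-12
            assert fps.count == _brute_force_root_count(model, float(alpha))


@given(alpha=st.floats(-2.0, 2.0))
def test_pitchfork_symmetry(alpha):
    """Pitchfork equilibria are symmetric under X -> -X, labels intact."""
    for model in ("pitchfork_supercritical", "pitchfork_subcritical"):
        fps = fixed_points(model, alpha)
        mirrored = sorted(
            ((-p.location, p.stability) for p in fps.points), key=lambda q: q[0]
        )
        assert mirrored == [(p.location, p.stability) for p in fps.points]


@given(alpha=st.floats(-2.0, 2.0).filter(lambda a: abs(a) > 1e-6))
def test_transcritical_stability_exchange(alpha):
    """X = 0 and X = alpha exchange stability as alpha crosses 0."""
    by_loc = {p.location: p.stability for p in fixed_points("transcritical", alpha).points}
    if alpha < 0:
        assert by_loc[0.0] == "stable" and by_loc[alpha] == "unstable"
    else:
        assert by_loc[0.0] == "unstable" and by_loc[alpha] == "stable"


SOLUTION_SAMPLES = [
    ("saddle_node", Theta(1.0, 1.5), 2.0),
    ("saddle_node", Theta(2.0, 0.3), 1.0),
    ("saddle_node", Theta(0.0, 1.0), 3.0),
    ("saddle_node", Theta(-1.0, 0.0), 0.5),
    ("transcritical", Theta(1.0, 0.5), 1.0),
    ("transcritical", Theta(-1.0, 0.5), 2.0),
    ("transcritical", Theta(0.0, 2.0), 4.0),
    ("pitchfork_supercritical", Theta(1.0, 0.5), 2.0),
    ("pitchfork_supercritical", Theta(-1.0, 1.5), 1.0),
    ("pitchfork_supercritical", Theta(0.0, 1.0), 2.0),
    ("pitchfork_subcritical", Theta(-1.0, 0.5), 2.0),
    ("pitchfork_subcritical", Theta(-1.0, -0.9), 1.0),
]


@pytest.mark.parametrize("model,theta,t", SOLUTION_SAMPLES)
def test_closed_form_satisfies_ode(model, theta, t):
    """Centred FD time derivative of X(t) matches the drift within 1e-6."""
    h = 1e-5
    x = closed_form_solution(model, theta, t)
    dxdt = (
        closed_form_solution(model, theta, t + h)
        - closed_form_solution(model, theta, t - h)
    ) / (2 * h)
    assert dxdt == pytest.approx(drift(model, x, theta.alpha), abs=1e-6)


def test_closed_form_constant_at_stable_fixed_point():
    assert closed_form_solution("transcritical", Theta(1.0, 1.0), 5.0) == pytest.approx(
        1.0, abs=1e-12
    )


def test_closed_form_long_time_limit():
    """Supercritical pitchfork converges to X_stable = sqrt(alpha)."""
    assert closed_form_solution(
        "pitchfork_supercritical", Theta(1.0, 0.5), 30.0
    ) == pytest.approx(1.0, abs=1e-9)


def test_closed_form_agrees_with_tiny_step_rk4():
    """Independent fine-step integration oracle (step 1e-5, t = 1)."""
    theta = Theta(1.0, 0.5)
    grid = TimeGrid(n_obs=2, t_end=1.0)
    traj = integrate("transcritical", theta, grid, SolverConfig(step=1e-5))
    exact = closed_form_solution("transcritical", theta, 1.0)
    assert traj.states[-1] == pytest.approx(exact, abs=1e-8)


@pytest.mark.parametrize(
    "model,theta,expected_tstar",
    [
        ("saddle_node", Theta(0.0, -1.0), 1.0),
        ("saddle_node", Theta(-1.0, 0.0), math.pi / 2),
        ("transcritical", Theta(1.0, -1.0), math.log(2.0)),
        ("pitchfork_subcritical", Theta(0.0, 1.0), 0.5),
        ("pitchfork_subcritical", Theta(1.0, 1.0), math.log(2.0) / 2),
    ],
)
def test_blow_up_error_carries_time(model, theta, expected_tstar):
    assert blow_up_time(model, theta) == pytest.approx(expected_tstar, rel=1e-12)
    with pytest.raises(BlowUpError) as err:
        closed_form_solution(model, theta, expected_tstar + 1.0)
    assert err.value.blow_up_time == pytest.approx(expected_tstar, rel=1e-12)


def test_stability_matches_linearisation_sign():
    """Stability labels follow the sign of f'(X*) from drift_dx."""
    for model in ALL_MODELS:
        for alpha in (-1.3, -0.2, 0.4, 1.7):
            for p in fixed_points(model, alpha).points:
                slope = drift_dx(model, p.location, alpha)
                if p.stability == "stable":
                    assert slope < -1e-10
                elif p.stability == "unstable":
                    assert slope > 1e-10
                else:
                    assert abs(slope) <= 1e-10
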