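"""Log-likelihood, likelihood surfaces and maximum-likelihood estimation."""

import numpy as np
import pytest

from bifinfer import (
    NoFiniteLikelihoodError,
    NoiseSpec,
    SolverConfig,
    Theta,
    TimeGrid,
    find_mle,
    generate_observation,
    likelihood_surface,
    log_likelihood,
    write_surface,
)


def test_self_likelihood_is_zero(saddle_obs_noiseless, grid1000):
    """Noiseless data scored at theta_true: zero residuals, the maximum."""
    ll = log_likelihood(Theta(1.0, 1.5), saddle_obs_noiseless, grid1000)
    assert ll.value == 0.0
    assert not ll.diverged


def test_constant_trajectory_worked_case(grid10):
    """Data constant at 1, candidate constant at 2, M = 10: exactly -5."""
    obs = generate_observation("saddle_node", Theta(1.0, 1.0), grid10, NoiseSpec(0.0), seed=0)
    ll = log_likelihood(Theta(4.0, 2.0), obs, grid10)
    assert ll.value == -5.0


def test_divergent_theta_gets_minus_inf(saddle_obs_noiseless, grid1000):
    ll = log_likelihood(Theta(-1.0, 0.0), saddle_obs_noiseless, grid1000)
    assert ll.value == -np.inf
    assert ll.diverged


def test_loglik_never_positive(saddle_obs_noiseless, grid1000):
    """-1/2 sum of squares: <= 0, equality only for zero residuals."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        theta = Theta(rng.uniform(0.1, 2.0), rng.uniform(0.5, 2.0))
        ll = log_likelihood(theta, saddle_obs_noiseless, grid1000)
        assert ll.value <= 0.0
        if theta != Theta(1.0, 1.5):
            assert ll.value < 0.0


def test_mismatched_time_grid_rejected(saddle_obs_noiseless):
    other = TimeGrid(n_obs=500)
    with pytest.raises(ValueError, match="do not match"):
        log_likelihood(Theta(1.0, 1.5), saddle_obs_noiseless, other)


def test_noisy_data_lowers_self_likelihood(grid1000):
    """At theta_true, noiseless data beat noisy data from the same run."""
    failures = 0
    for seed in range(20):
        clean = generate_observation(
            "saddle_node", Theta(1.0, 1.5), grid1000, NoiseSpec(0.0), seed=seed
        )
        noisy = generate_observation(
            "saddle_node", Theta(1.0, 1.5), grid1000, NoiseSpec(0.1), seed=seed
        )
        ll_clean = log_likelihood(Theta(1.0, 1.5), clean, grid1000).value
        ll_noisy = log_likelihood(Theta(1.0, 1.5), noisy, grid1000).value
        if not ll_clean > ll_noisy:
            failures += 1
    assert failures <= 1


def test_surface_argmax_at_true_cell(saddle_obs_noiseless, grid1000):
    alpha_axis = np.linspace(0.0, 2.0, 21)  # contains 1.0
    ic_axis = np.linspace(0.5, 2.5, 21)  # contains 1.5
    surf = likelihood_surface("saddle_node", saddle_obs_noiseless, alpha_axis, ic_axis, grid1000)
    assert surf.argmax == Theta(1.0, 1.5)
    assert surf.loglik.shape == (21, 21)
    i = np.nonzero(ic_axis == 1.5)[0][0]
    j = np.nonzero(alpha_axis == 1.0)[0][0]
    assert surf.loglik[i, j] == 0.0


def test_all_divergent_subgrid_raises(saddle_obs_noiseless, grid1000):
    """Saddle-node alpha < 0 everywhere: no finite likelihood anywhere."""
    alpha_axis = np.linspace(-2.0, -0.1, 10)
    ic_axis = np.linspace(-2.0, 2.0, 10)
    with pytest.raises(NoFiniteLikelihoodError):
        likelihood_surface(
            "saddle_node", saddle_obs_noiseless, alpha_axis, ic_axis, grid1000
        )


def test_supercritical_surface_mirror_equivariance(grid1000):
    """Data from (a0, -IC0) gives the IC-mirrored surface of (a0, IC0)."""
    alpha_axis = np.linspace(0.2, 1.8, 9)
    ic_axis = np.linspace(-1.6, 1.6, 9)
    surf_pos = likelihood_surface(
        "pitchfork_supercritical",
        generate_observation(
            "pitchfork_supercritical", Theta(1.0, 0.7), grid1000, NoiseSpec(0.0), seed=0
        ),
        alpha_axis,
        ic_axis,
        grid1000,
    )
    surf_neg = likelihood_surface(
        "pitchfork_supercritical",
        generate_observation(
            "pitchfork_supercritical", Theta(1.0, -0.7), grid1000, NoiseSpec(0.0), seed=0
        ),
        alpha_axis,
        ic_axis,
        grid1000,
    )
    assert np.allclose(surf_pos.loglik, surf_neg.loglik[::-1, :], atol=1e-9)


def test_mle_exact_recovery_noiseless(saddle_obs_noiseless):
    res = find_mle("saddle_node", saddle_obs_noiseless, (-2.0, 2.0), (-2.0, 2.0))
    assert abs(res.theta_hat.alpha - 1.0) < 1e-3
    assert abs(res.theta_hat.ic - 1.5) < 1e-3
    assert res.loglik_at_hat.value <= 0.0
    assert res.n_evaluations > 41 * 41


def test_mle_reproducible(saddle_obs_noiseless):
    a = find_mle("saddle_node", saddle_obs_noiseless, (-2.0, 2.0), (-2.0, 2.0))
    b = find_mle("saddle_node", saddle_obs_noiseless, (-2.0, 2.0), (-2.0, 2.0))
    assert a.theta_hat == b.theta_hat
    assert a.n_evaluations == b.n_evaluations


def test_mle_in_divergent_region_raises(saddle_obs_noiseless):
    with pytest.raises(NoFiniteLikelihoodError):
        find_mle("saddle_node", saddle_obs_noiseless, (-2.0, -0.5), (-2.0, 2.0))


def test_mle_never_below_surface_argmax(grid1000):
    """Refinement can only improve on the coarse-grid optimum."""
    obs = generate_observation(
        "saddle_node", Theta(1.0, 1.5), grid1000, NoiseSpec(0.1), seed=4
    )
    bounds = ((-2.0, 2.0), (-2.0, 2.0))
    surf = likelihood_surface(
        "saddle_node",
        obs,
        np.linspace(*bounds[0], 41),
        np.linspace(*bounds[1], 41),
        grid1000,
    )
    best_grid = surf.loglik[np.isfinite(surf.loglik)].max()
    res = find_mle("saddle_node", obs, bounds[0], bounds[1])
    assert res.loglik_at_hat.value >= best_grid


def test_surface_export(tmp_path, saddle_obs_noiseless, grid1000):
    import pandas as pd

    surf = likelihood_surface(
        "saddle_node",
        saddle_obs_noiseless,
        np.linspace(0.0, 2.0, 5),
        np.linspace(0.5, 2.5, 5),
        grid1000,
    )
    path = tmp_path / "surf.csv"
    write_surface(surf, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["alpha", "ic", "loglik", "diverged"]
    assert len(df) == 25
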