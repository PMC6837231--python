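# Methods

## Models

The package studies the four scalar co-dimension 1 bifurcation normal
forms, dX/dt = f(X; α) with f = α − X², αX − X², αX − X³ and αX + X³.
Equilibria and their stability are computed analytically (the drifts are
fixed quadratics/cubics, so numerical root finding would add error for no
generality): a root X* is stable when f′(X*) < 0, unstable when
f′(X*) > 0, and *marginal* when |f′(X*)| ≤ 1e−10.  The marginal band
exists to classify the exact bifurcation points (the α = 0 double roots)
without floating-point misclassification of nearby hyperbolic points.

For the transcritical form at α < 0 the unstable equilibrium is X = α
(and X = 0 is stable), as the linearisation f′(X) = α − 2X gives
f′(α) = −α > 0; the labels exchange at α = 0.

All four ODEs admit closed-form solutions (the transcritical form is
logistic; both pitchforks are Bernoulli equations in u = X⁻²; the
saddle-node solves in tanh/tan form, with the α = 0 limits X₀/(1 + X₀t)).
These are implemented with their exact finite blow-up times and serve as
independent oracles for the numerical integrator; their own correctness
is checked two independent ways — a centred finite-difference time
derivative must satisfy the ODE, and a tiny-step (1e−5) RK4 run must
agree to 1e−8.

## Simulation

Trajectories use the classic fixed-step fourth-order Runge–Kutta method.
Observation times are M evenly spaced points spanning [0, 10]; the
internal step (default 1e−3) is rounded down so that each observation
interval is an integer number of internal steps, hence observation times
are hit exactly, never interpolated.  Defaults and the reasoning:

| parameter | default | why |
|---|---|---|
| time window | t ∈ [0, 10] | for \|α\|, \|IC\| ≤ 2 every converging trajectory is within ~1e−6 of its equilibrium by t = 10 (verified against the closed forms) |
| internal RK4 step | 1e−3 (time units) | integration error ~1e−13, many orders below the studied noise levels |
| divergence threshold | \|X\| > 1e6 | every escaping trajectory of these drifts blows up in finite time, so the diverged/ok call is insensitive to this bound (property-tested at 1e4 vs 1e8) |

Divergence is checked after every *internal* step, so blow-up between
sparse (M = 10) observations is still caught.  A diverged trajectory
carries the first crossing time and is a status, never an exception: grid
scans must traverse divergent regions without aborting.  The RK4 core is
a numba-compiled kernel; whole-plane scans batch tens of thousands of
trajectories through it.

## Synthetic observations

An observation is the RK4 solution at the M observation times plus
i.i.d. N(0, σ²) noise added per time point after solving.  Named levels:
low σ = 0, moderate σ = 0.1, heavy σ = 1.0; named sampling densities
M = 1000, 500, 10.  One integer seed feeds one dedicated `numpy`
Generator per observation, making every dataset bit-reproducible; the
CSV export uses hexadecimal floats so round-trips are bit-exact.  Only
additive Gaussian noise is implemented; multiplicative/log-normal noise
and irregular sampling are out of scope.

## Likelihood and MLE

ln L(θ|D) = −½ Σᵢ₌₁..ᴹ (yᵢ − μᵢ(θ))², the Gaussian log-likelihood with
the constant dropped and no 1/σ² factor — the MLE location is unaffected
and surfaces keep an interpretable 0 maximum for noiseless self-data.
Divergent θ map to −inf rather than a large finite penalty: such regions
are non-inferable by construction and −inf keeps them out of any argmax.
Surface argmax ties break deterministically (smallest α, then smallest
IC).

`find_mle` runs a 41×41 coarse grid over the bounds, then Nelder–Mead
(function evaluations only — the likelihood is non-smooth at divergence
boundaries, so gradient methods are inappropriate) from the best cell,
clamped to the bounds via an out-of-bounds penalty of +inf, and never
returns a value below the coarse-grid optimum.  Everything is
deterministic for fixed inputs.

## Observed Fisher information

FI_obs(θ) = −tr(H) where H is the Hessian of the log-likelihood at θ,
estimated by central differences: 3-point stencils for H_αα and H_ICIC,
the 4-point cross stencil for the mixed entry, default step 1e−3 in both
coordinates.  The step balances truncation against cancellation for
log-likelihoods built from ~1e3 squared residuals and is validated
against a Richardson-extrapolated oracle (steps 1e−2 and 5e−3) to 1e−3
relative accuracy.

Whole-plane maps evaluate each θ against its **own noiseless
simulation**: θ is then the exact MLE of the data it is scored on, the
centre log-likelihood is exactly 0, and the curvature measures the local
inferability of that parameter combination.  This is the only reading
under which a plane-wide "observed FI" map is well defined, and it
reproduces the expected structure: FI enriched at the bifurcation point
and along unstable equilibria, zero over divergent regions.

Conventions:

* a stencil touching a divergent neighbour is classified
  `divergent_set_zero` even when θ itself converges — this matches the
  zeroing of divergent regions and avoids one-sided-difference bias at
  basin boundaries; the affected margin is at most one FD step;
* raw traces are stored (tiny negative values from FD error are
  preserved for numerical honesty); `clamped()` floors them at 0 for
  export and plotting;
* the marginal fixed-IC slice is by default a row of the full 2×2-trace
  map; "marginalized" could equally mean the pure α-curvature −H_αα, so
  that variant is available as `mode="alpha_only"` and the choice is
  recorded in output metadata;
* default map extent α, IC ∈ [−2, 2] at 101×101 (tests and examples use
  41×41, which preserves all the structure at a fraction of the cost).

Absolute FI magnitudes scale with the observation count and the
integration window and are therefore reported as relative structure
(peak locations, symmetry, ordering between models), not as absolute
values to compare across studies.

## What the synthetic study does and does not show

The generator emulates dense-to-sparse, clean-to-noisy observation of a
*deterministic* one-dimensional system with additive i.i.d. Gaussian
measurement error.  Passing tests therefore demonstrate: correct
bifurcation structure, integrator accuracy against exact solutions,
exactness of the likelihood on constructed cases, FD Hessians validated
against extrapolation oracles, the qualitative FI geography (peaks at
bifurcation events and unstable equilibria; symmetry of the pitchfork
maps; the fully-inferable transcritical positive quadrant; the
subcritical convergence basin |IC| < √(−α)), and graceful degradation of
MLE recovery under noise and sparsity.

They do **not** speak to: intrinsic (process) stochasticity — noise here
never feeds back into the dynamics, which matters especially near basin
boundaries; model misspecification (the fitted model is always the
generating model); multivariate systems or co-dimension ≥ 2 bifurcations;
oscillatory (Hopf) dynamics; or non-Gaussian measurement error.

## Test-suite problem sizes

Unit and property tests run at M ≤ 1000 with small grids; the structural
map checks use 41×41 grids at M = 1000 (the full default resolution adds
nothing qualitative); MLE robustness uses 5 seeds per (σ, M) combination
and parameter recovery 20 seeds.  The recovery tolerances (median
componentwise error 0.011 in α, 0.023 in IC) were frozen at twice the
medians achieved by an independent brute-force refined grid search run
before the estimator was built.
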