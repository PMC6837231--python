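# bifinfer

**Parameter inferability around co-dimension 1 bifurcations.**

Many biological dynamical systems — cell-fate switches, epidemic
thresholds, ecological tipping points — sit near bifurcations: points in
parameter space where a small change in one parameter qualitatively
changes the long-run behaviour.  `bifinfer` asks the practical question
this raises for modellers: *how does the presence of a bifurcation shape
our ability to infer the model's parameters from time-series data?*

It studies the four canonical scalar (co-dimension 1) normal forms,

| bifurcation             | ODE                        | structure at α = 0 |
|-------------------------|----------------------------|--------------------|
| saddle-node             | dX/dt = α − X²             | equilibria appear (±√α for α > 0; none for α < 0) |
| transcritical           | dX/dt = αX − X²            | branches X = 0 and X = α exchange stability |
| supercritical pitchfork | dX/dt = αX − X³            | stable 0 splits into ±√α |
| subcritical pitchfork   | dX/dt = αX + X³            | unstable ±√(−α) merge into unstable 0 |

and quantifies inferability of θ = (α, IC) — the bifurcation parameter
and the initial condition, inferred jointly — through three linked tools:

1. **Synthetic data.** Fixed-step fourth-order Runge–Kutta solutions
   sampled at M ∈ {1000, 500, 10} time points, with i.i.d. Gaussian
   measurement noise (σ ∈ {0, 0.1, 1.0}) added per time point after
   solving.  Trajectories that blow up in finite time are flagged as
   divergent rather than fitted.
2. **Log-likelihood.** Under i.i.d. Gaussian noise,
   `ln L(θ|D) = −½ Σᵢ (yᵢ − μᵢ(θ))²` up to a constant, where μᵢ(θ) is the
   simulated solution at observation time tᵢ.  Surfaces over the (α, IC)
   plane and a grid-plus-Nelder–Mead maximum-likelihood estimator are
   provided; divergent θ get `−inf` (explicitly non-inferable).
3. **Observed Fisher information.**
   `FI_obs(θ) = −tr(Hessian(ln L(θ|D)))`, estimated by central finite
   differences of the log-likelihood, with each grid point evaluated
   against its own noiseless simulation (so θ is the exact MLE of the
   data it is scored on).  Whole-plane maps and marginal fixed-IC slices
   reveal where parameters are reliably inferable: FI is enriched at the
   bifurcation point and along unstable equilibrium branches, and set to
   0 where the system diverges.

## Worked example

```python
import numpy as np
from bifinfer import (Theta, TimeGrid, NoiseSpec, generate_observation,
                      find_mle, fisher_slice)

grid = TimeGrid(n_obs=1000)                       # t in [0, 10]
obs = generate_observation("saddle_node", Theta(1.0, 1.5), grid,
                           NoiseSpec(0.1), seed=2)
res = find_mle("saddle_node", obs, (-2, 2), (-2, 2))
print(res.theta_hat)          # Theta(alpha=0.9948..., ic=1.5051...)

row = fisher_slice("saddle_node", 1.5, np.linspace(-2, 2, 41), grid)
fi = np.array([max(v.trace_fi, 0) for _, v in row])
print(np.linspace(-2, 2, 41)[fi.argmax()])        # 0.0
```

With moderate noise (σ = 0.1) on 1000 points the MLE lands within ~0.01
of the true (α, IC) = (1, 1.5).  The marginal Fisher-information slice at
IC = 1.5 peaks at α = 0: at the bifurcation even tiny changes in α flip
the system between converging and diverging, so data are maximally
informative there.  At IC = −1.0 the peak instead sits at α = 1, where
the IC touches the unstable equilibrium −√α.  The `examples/` scripts
walk through each capability and print these numbers.

## Command line

```bash
bifinfer observe --model saddle_node --alpha 1 --ic 1.5 --level moderate \
    --seed 1 --out-dir runs/obs
bifinfer fisher-map --model pitchfork_supercritical --resolution 41 \
    --out-dir runs/fmap
```

Subcommands: `simulate`, `observe`, `loglik-surface`, `fisher-map`,
`fisher-slice`, `mle`.  Settings come from a flat YAML file (`--config`)
overridden by flags; every output ships a JSON metadata sidecar with the
full effective configuration, so a run can be replayed exactly.

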