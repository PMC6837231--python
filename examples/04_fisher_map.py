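"""Observed Fisher information across the (alpha, IC) plane.

For every grid point theta the package simulates noiseless data at theta
itself (so theta is the exact MLE of its own data) and measures the trace
of the negative log-likelihood Hessian there — a scalar map of how
sharply the data pin down (alpha, IC).  Divergent parameter combinations
get FI = 0.  Marginal slices at fixed IC show the peaks sitting at the
bifurcation point and along the unstable equilibrium branch.
"""

import numpy as np

from bifinfer import TimeGrid, fisher_map, fisher_slice

grid = TimeGrid(n_obs=1000)
ax = np.linspace(-2, 2, 41)

fmap = fisher_map("saddle_node", ax, ax, grid)
print(f"saddle-node map: {fmap.divergent.sum()} of {fmap.trace.size} cells divergent")
print(f"max FI = {fmap.clamped().max():.3g}")

for ic in (1.5, -1.0):
    row = fisher_slice("saddle_node", ic, ax, grid)
    alphas = np.array([a for a, _ in row])
    fi = np.array([max(v.trace_fi, 0.0) for _, v in row])
    print(f"IC = {ic:+.1f}: FI peaks at alpha = {alphas[fi.argmax()]:+.2f}")

print(
    "\nReading: at IC = 1.5 the peak sits at the bifurcation (alpha = 0) — "
    "tiny changes in alpha flip the system between diverging and "
    "converging, so the data are maximally informative there.  At "
    "IC = -1.0 the peak shifts to alpha = IC^2 = 1, where the IC touches "
    "the unstable equilibrium -sqrt(alpha)."
)
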