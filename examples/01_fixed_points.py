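"""Bifurcation structure of the four normal forms.

Scans the bifurcation parameter alpha and prints how the equilibria of
each normal form appear, disappear, or exchange stability as alpha
crosses 0 — the qualitative skeleton that shapes everything downstream.
"""

from bifinfer import fixed_points

MODELS = [
    "saddle_node",
    "transcritical",
    "pitchfork_supercritical",
    "pitchfork_subcritical",
]

for model in MODELS:
    print(f"\n{model}")
    for alpha in (-1.0, 0.0, 1.0):
        fps = fixed_points(model, alpha)
        desc = ", ".join(f"X*={p.location:+.3g} ({p.stability})" for p in fps.points)
        print(f"  alpha = {alpha:+.1f}: {fps.count} equilibria  {desc or '(none)'}")

print(
    "\nReading: the saddle-node has no equilibria for alpha < 0 (all "
    "trajectories diverge), the transcritical branches swap stability at "
    "alpha = 0, and the pitchforks split symmetrically about X = 0."
)
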