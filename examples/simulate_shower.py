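"""Monte-Carlo obstruction from a shower of emboli in a Murray's-law tree.

Injects a bypass-like shower of small bubbles followed by a burst of
0.5-1 mm macrobubbles into a 12-generation tree (a reduced-depth stand-in
for the full 19-generation MCA territory, which takes minutes per run) and
prints the ensemble mean and 95% CI of the peak percentage of unperfused
terminal arterioles.
"""

import numpy as np

from airemboli import SimParams, build_tree, run_ensemble

rng = np.random.default_rng(5)
small = list(zip(np.sort(rng.uniform(0.0, 60.0, 300)),
                 rng.lognormal(np.log(28.0), 0.814, 300)))
big = list(zip(np.sort(rng.uniform(60.0, 80.0, 10)),
               rng.uniform(500.0, 1000.0, 10)))

tree = build_tree(3.0, generations=12)
params = SimParams(ensemble_size=8, rng_seed=42)
series = run_ensemble(sorted(small + big), tree, params, t_end=180.0)

peak_idx = int(np.argmax(series.mean_percent))
print(f"tree: root 3.0 mm, {tree.generations} generations, "
      f"{tree.n_terminals} terminal arterioles of {tree.diameter(12) * 1e6:.0f} um")
print(f"schedule: 300 bypass-size bubbles + 10 macrobubbles over 80 s")
print(f"peak obstruction: {series.mean_percent[peak_idx]:.3f}% "
      f"(95% CI {series.ci_low[peak_idx]:.3f}-{series.ci_high[peak_idx]:.3f}%) "
      f"at t = {series.times[peak_idx]:.1f} s")
print(f"end of run:       {series.mean_percent[-1]:.3f}% at t = {series.times[-1]:.0f} s")
print(
    "\nThe small bubbles pass through or dissolve without lodging; nearly"
    "\nall of the obstruction is carried by the few macrobubbles, which"
    "\nlodge generations above the terminals and clear only slowly."
)
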