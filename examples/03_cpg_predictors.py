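"""Feedback prediction by morphed oscillators.

Generates 50 quasi-periodic cycles of synthetic interneuron signals
(2% period jitter, 2% amplitude noise), extracts each pathway's shaping
function from the first 40 cycles, runs the oscillators passively —
synchronized only by the touchdown/takeoff events — over the held-out
cycles, and prints the per-pathway reproduction correlations.
"""

from neurogait.analysis import passive_reproduction_correlations
from neurogait.synthetic import make_synthetic_gait

gait = make_synthetic_gait(period=1.0, jitter=0.02, noise=0.02,
                           n_cycles=50, seed=1)
res = passive_reproduction_correlations(gait, train_cycles=40)

worst = sorted(res["per_pathway"].items(), key=lambda kv: kv[1])[:5]
for (limb, name), r in worst:
    print(f"  limb {'LR'[limb]}  {name:<18s} r = {r:.4f}")
print(f"minimum correlation over 18 pathways: {res['min']:.4f}")
print("Near-1 correlations mean each reflex signal of a steady gait is "
      "predictable from phase alone — the premise of using CPGs as "
      "feedback predictors.")
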