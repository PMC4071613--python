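# neurogait

A planar neuromuscular model of human walking for researchers in
computational motor control and neuromechanics.  The package implements
a reflex-driven musculoskeletal biped — seven rigid segments actuated by
seven Hill-type muscle–tendon units per leg, controlled by fifteen
delayed feedback pathways per limb and a stance/swing state machine —
and extends it with a central-pattern-generator (CPG) layer in which
*feedforward predictors* of the feedback signals can progressively
replace them, modulated by two low-dimensional supraspinal commands.

## The model in brief

Muscle stimulation is produced in clamped affine stages.  For limb state
`s` (stance, swing, or double-support finishing stance, resolved from
the 0.1 body-weight foot-load threshold):

    X_in_sen = min{1, max{0, W ~X_sen}}            (delayed sensors -> interneurons)
    X_mn     = G^s X_in_sen + X0_mn                (state-gated motoneurons)
    X_mtu    = clamp(~X_mn, 0.01, 1)               (stimulation with tone floor)
    dA/dt    = tau_A (X_mtu - A),  tau_A = 100/s   (excitation-contraction)
    F_CE     = F_max f_l(l_CE) f_v(v_CE) A,  F_m = F_SE = F_CE + F_PE - F_BE

Joint soft limits follow the nonlinear spring–damper
`tau = k dphi (1 + omega/omega_ref)` (k = 17.19 N·m/rad,
omega_ref = 1.74e-2 rad/s) engaging only beyond the range.  The CPG
layer blends each muscle-sensor pathway with a predictor:

    X_mn = G^s (alpha X_in_sen + (1 - alpha) X_in_cpg) + X0_mn

where `X_in_cpg` is either a constant (the signal's active-phase mean)
or a morphed oscillator `x' = gamma (g(theta) - x) + g'(theta) theta'`
whose shaping function g is the spline-fitted mean cycle of the
recorded signal, synchronized to touchdown/takeoff events with a
slowing-down mechanism that keeps theta <= 1.  With alpha = 1 the hybrid
model degenerates exactly (bitwise, in this implementation) to the pure
reflex model.  Controller gains are found by a lexicographic particle
swarm (distance -> speed -> knee loading -> metabolic energy, worst of
five random slope environments).

See `docs/methods.md` for assumptions, parameter tables, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from neurogait.analysis import passive_reproduction_correlations
from neurogait.synthetic import make_synthetic_gait
from neurogait.plant import soft_limit_torque

# ligament soft limit: 1 rad beyond the range at zero speed
print(soft_limit_torque(1.0, 0.0))          # 17.19  [N·m]

# how well do morphed oscillators predict steady-gait reflex signals?
gait = make_synthetic_gait(period=1.0, jitter=0.02, noise=0.02,
                           n_cycles=50, seed=1)
res = passive_reproduction_correlations(gait, train_cycles=40)
print(round(res["min"], 4))                 # 0.998
```

The first number is the ligament spring stiffness expressed at one
radian of overshoot — the worked check of the soft-limit law.  The
second is the minimum, over all 18 muscle-sensor pathways, of the
correlation between a steady synthetic gait's interneuron signals and
their oscillator reproductions run passively on held-out cycles: close
to 1, meaning the feedback of a periodic gait is predictable from gait
phase alone, which is the premise of the whole feedforward extension.

The `examples/` directory holds one short script per capability
(isolated muscle rig, reflex episode, predictor extraction, supraspinal
modulation, lexicographic PSO, gait-harmony analytics); each prints the
numbers it computes and a line on what they mean.  A thin CLI wraps the
episode runner: `neurogait simulate --seed 0 --duration 5 --out log.csv`,
`neurogait analyze --log log.csv`, `neurogait make-gait-signals
--seed 0 --out signals.csv`.

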