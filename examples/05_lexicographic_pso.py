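"""Lexicographic particle swarm on a two-stage toy problem.

Stage 0 is a constraint (reach x0 > 0), stage 1 the real objective
(minimize x1^2).  Candidates are ranked by (stage reached, stage
fitness): any candidate satisfying the constraint beats every candidate
that does not, regardless of the objective values — the mechanism that
lets the walking optimizer demand "covers 20 m" before it ever looks at
speed, knee loading or energy.
"""

import numpy as np

from neurogait.optimize import PsoConfig, StageSpec, pso_optimize

stages = (StageSpec("constraint", "max", 0.0),
          StageSpec("objective", "min", None))


def objective(x):
    if x[0] > 0.0:
        return (1, float(x[1] ** 2))
    return (0, float(x[0]))


best, score, history = pso_optimize(
    objective, (np.array([-1.0, -2.0]), np.array([1.0, 2.0])), seed=1,
    config=PsoConfig(n_particles=20, n_iters=60), stages=stages)

print(f"best position: x0 = {best[0]:+.4f} (constraint x0 > 0), "
      f"x1 = {best[1]:+.2e}")
print(f"best score: stage {score[0]}, value {score[1]:.2e}")
reached = next(i for i, (s, _) in enumerate(history) if s == 1)
print(f"the swarm entered the feasible stage at iteration {reached} and "
      f"then minimized the stage-1 objective only")
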