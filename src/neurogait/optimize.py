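"""Lexicographic multi-stage particle swarm optimization.

The controller's 25 open parameters (per-muscle basal activities, trunk
reference angle, muscle-length feedback offsets and the nonzero reflex
gains, shared between the two mirrored limbs) are optimized through a
sequence of constraint stages: (1) cover at least ``d_lim`` metres,
(2) hold the target speed, (3) minimize a knee-overextension penalty,
(4) minimize metabolic energy.  Every candidate is scored by the tuple
``(stage_reached, stage_fitness)``; a candidate in a higher stage always
ranks above one in a lower stage, and ties within a stage are broken by
that stage's objective in its own sense.  Each evaluation runs on five
independently seeded slope environments and keeps only the worst tuple.

The swarm uses the canonical constriction constants (inertia 0.729,
cognitive = social = 1.494), velocity clamped at 20% of each range, and
reflecting walls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import EpisodeConfig, TrajectoryLog, generate_slope_environment, run_episode
from .muscle import MUSCLE_NAMES, MuscleBank
from .reflex import (DEFAULT_BASAL, DEFAULT_THETA_REF, ReflexController,
                     build_default_pathways)

__all__ = [
    "StageSpec",
    "ParticleState",
    "PsoConfig",
    "DEFAULT_STAGES",
    "PARAMETER_MANIFEST",
    "lexicographic_rank",
    "worst_of",
    "evaluate_candidate",
    "pso_optimize",
    "knee_overextension_penalty",
    "metabolic_energy",
    "controller_from_params",
    "default_parameter_bounds",
]


# ---------------------------------------------------------------------------
# stages and ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One optimization stage: an objective plus, for every stage except
    the last, the constraint that advances a candidate past it."""

    name: str
    sense: str  # 'max' | 'min'
    threshold: float | None = None  # None => final stage

    def satisfied(self, value: float) -> bool:
        if self.threshold is None:
            return False
        return (value >= self.threshold if self.sense == "max"
                else value <= self.threshold)


#: distance -> speed -> knee penalty -> metabolic energy
DEFAULT_STAGES: tuple[StageSpec, ...] = (
    StageSpec("distance", "max", 20.0),  # cover d_lim metres
    StageSpec("speed_error", "min", 0.05),  # | v - 1.3 | [m/s]
    StageSpec("knee_penalty", "min", 10.0),  # [N*m*s]
    StageSpec("energy", "min", None),
)

SPEED_TARGET = 1.3  # [m/s]


def lexicographic_rank(a: tuple[int, float], b: tuple[int, float],
                       stages: tuple[StageSpec, ...] = DEFAULT_STAGES) -> int:
    """Compare two (stage, value) tuples.

    Returns -1 if ``a`` is fitter, +1 if ``b`` is fitter, 0 on a tie.
    A higher stage always wins; within a stage the stage's sense
    decides.
    """
    sa, va = a
    sb, vb = b
    if sa != sb:
        return -1 if sa > sb else 1
    if va == vb:
        return 0
    better = va > vb if stages[sa].sense == "max" else va < vb
    return -1 if better else 1


def worst_of(tuples, stages: tuple[StageSpec, ...] = DEFAULT_STAGES
             ) -> tuple[int, float]:
    """Lexicographic minimum of evaluation tuples (the worst case)."""
    worst = None
    for t in tuples:
        if worst is None or lexicographic_rank(t, worst, stages) < 0:
            worst = t
    if worst is None:
        raise ValueError("empty evaluation set")
    return worst


# ---------------------------------------------------------------------------
# stage fitness ingredients
# ---------------------------------------------------------------------------

def knee_overextension_penalty(log: TrajectoryLog) -> float:
    """Time integral of the knee ligament torque magnitude [N·m·s].

    Zero for a gait that never drives the knee past its soft limit;
    strictly increasing with deeper or longer over-travel.
    """
    return float(np.sum(np.abs(log.knee_lig)) * log.dt)


#: Bhargava-style energy constants (documented package defaults)
_SIGMA = 0.25e6  # specific muscle tension [N/m^2]
_RHO = 1059.7  # muscle density [kg/m^3]
_ACT_HEAT = 40.0  # activation+maintenance heat rate [W/kg] at full drive
_SHORT_HEAT = 0.25  # shortening heat per unit CE force and speed


def metabolic_energy(log: TrajectoryLog, muscles: MuscleBank | None = None,
                     model: str = "bhargava") -> float:
    """Metabolic energy of an episode [J].

    ``model='bhargava'``: per-muscle decomposition into activation +
    maintenance heat (proportional to muscle mass and activation),
    shortening heat and positive mechanical CE work.  ``model='stim2'``
    is the cheap fallback, the time integral of the summed squared
    stimulations (arbitrary units).  Both are nonnegative and additive
    over time.
    """
    if model == "stim2":
        return float(np.sum(log.m_stim ** 2) * log.dt)
    if model != "bhargava":
        raise ValueError(f"unknown energy model {model!r}")
    muscles = muscles or MuscleBank(tuple(_default_muscle_pair()))
    mass = _RHO * muscles.l_opt * muscles.f_max / _SIGMA  # [kg] per MTU
    heat = _ACT_HEAT * mass[None, :] * log.m_act  # [W]
    f_ce = np.maximum(log.m_force, 0.0)
    shortening = np.maximum(-log.m_vce, 0.0)
    short_heat = _SHORT_HEAT * f_ce * shortening  # [W]
    work = f_ce * shortening  # positive CE work [W]
    power = heat + short_heat + work
    return float(np.sum(power) * log.dt)


def _default_muscle_pair():
    from .muscle import DEFAULT_MUSCLES
    return DEFAULT_MUSCLES + DEFAULT_MUSCLES


# ---------------------------------------------------------------------------
# the 25-parameter manifest
# ---------------------------------------------------------------------------

#: (name, lower, upper, default) for every open parameter.  7 basal
#: activities + trunk reference angle + 3 length-feedback offsets + 14
#: reflex gains (6 force + 3 length + balance kp/kd + contralateral-load,
#: trunk-lean and knee-overextension gains) = 25, shared across limbs.
PARAMETER_MANIFEST: tuple[tuple[str, float, float, float], ...] = (
    *[(f"basal_{m}", 0.0, 0.3, DEFAULT_BASAL[m]) for m in MUSCLE_NAMES],
    ("theta_ref", 0.0, 0.3, DEFAULT_THETA_REF),
    ("loff_TA", 0.4, 1.1, 0.71),
    ("loff_HAM", 0.4, 1.2, 0.85),
    ("loff_HF", 0.4, 1.1, 0.65),
    ("gain_GAS<-GAS", 0.0, 3.0, 1.10),
    ("gain_GLU<-GLU", 0.0, 2.0, 0.40),
    ("gain_HAM<-HAM", 0.0, 2.0, 0.65),
    ("gain_SOL<-SOL", 0.0, 3.0, 1.20),
    ("gain_TA<-SOL", 0.0, 2.0, 0.60),
    ("gain_VAS<-VAS", 0.0, 3.0, 1.15),
    ("gain_TA<-TA", 0.0, 3.0, 1.10),
    ("gain_HF<-HAM", 0.0, 2.0, 0.65),
    ("gain_HF<-HF", 0.0, 2.0, 0.35),
    ("gain_GSIF_kp", 0.0, 4.0, 1.50),
    ("gain_GSIF_kd", 0.0, 1.0, 0.25),
    ("gain_GCF", 0.0, 4.0, 2.00),
    ("gain_TLF", 0.0, 2.0, 0.50),
    ("gain_KNEE_OPF", 0.0, 6.0, 2.00),
)

_GAIN_PATHWAY = {
    "gain_GAS<-GAS": "GAS<-GAS MFF ST", "gain_GLU<-GLU": "GLU<-GLU MFF SW",
    "gain_HAM<-HAM": "HAM<-HAM MFF SW", "gain_SOL<-SOL": "SOL<-SOL MFF ST",
    "gain_TA<-SOL": "TA<-SOL MFF ST", "gain_VAS<-VAS": "VAS<-VAS MFF ST",
    "gain_TA<-TA": "TA<-TA MLF CY", "gain_HF<-HAM": "HF<-HAM MLF SW",
    "gain_HF<-HF": "HF<-HF MLF SW", "gain_GCF": "VAS<-GCF STend",
    "gain_TLF": "HF<-TLF SW", "gain_KNEE_OPF": "VAS<-KNEE OPF",
}
_LOFF_PATHWAY = {"loff_TA": "TA<-TA MLF CY", "loff_HAM": "HF<-HAM MLF SW",
                 "loff_HF": "HF<-HF MLF SW"}


def default_parameter_bounds() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([p[1] for p in PARAMETER_MANIFEST])
    hi = np.array([p[2] for p in PARAMETER_MANIFEST])
    return lo, hi


def default_parameter_vector() -> np.ndarray:
    return np.array([p[3] for p in PARAMETER_MANIFEST])


def controller_from_params(x: np.ndarray, dt: float = 1e-3) -> ReflexController:
    """Instantiate the reflex controller from a 25-parameter vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(PARAMETER_MANIFEST),):
        raise ValueError(f"expected {len(PARAMETER_MANIFEST)} parameters")
    values = {name: float(v) for (name, *_), v in zip(PARAMETER_MANIFEST, x)}
    basal = {m: values[f"basal_{m}"] for m in MUSCLE_NAMES}
    pathways = []
    for p in build_default_pathways():
        gain = p.gain
        l_off = p.l_off
        kd = p.kd
        for key, pname in _GAIN_PATHWAY.items():
            if pname == p.name:
                gain = values[key]
        if p.sensor_type == "3+4":
            gain = values["gain_GSIF_kp"]
            kd = values["gain_GSIF_kd"]
        for key, pname in _LOFF_PATHWAY.items():
            if pname == p.name:
                l_off = values[key]
        pathways.append(replace(p, gain=gain, l_off=l_off, kd=kd))
    return ReflexController(pathways, basal, values["theta_ref"], dt=dt)


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

def stage_tuple_from_log(log: TrajectoryLog,
                         stages: tuple[StageSpec, ...] = DEFAULT_STAGES,
                         energy_model: str = "stim2") -> tuple[int, float]:
    """(stage, value) of one episode under the staged constraints."""
    duration = log.times[-1] - log.times[0] if log.n_steps > 1 else 1e-9
    speed = log.distance / max(duration, 1e-9)
    metrics = {
        "distance": log.distance,
        "speed_error": abs(speed - SPEED_TARGET),
        "knee_penalty": knee_overextension_penalty(log),
        "energy": metabolic_energy(log, model=energy_model),
    }
    stage = 0
    for spec in stages:
        if spec.satisfied(metrics[spec.name]):
            stage += 1
        else:
            break
    stage = min(stage, len(stages) - 1)
    return stage, metrics[stages[stage].name]


def evaluate_candidate(x: np.ndarray, seed: int,
                       stages: tuple[StageSpec, ...] = DEFAULT_STAGES,
                       duration: float = 20.0, n_envs: int = 5,
                       energy_model: str = "stim2") -> tuple[int, float]:
    """Worst-of-``n_envs`` staged evaluation of one parameter vector.

    Five randomized slope environments are generated from the seed; the
    candidate's tuple is the lexicographic minimum over them, so a
    single bad environment dictates the score.
    """
    rng = np.random.default_rng(seed)
    env_seeds = rng.integers(0, 2 ** 31 - 1, size=n_envs)
    tuples = []
    for es in env_seeds:
        env = generate_slope_environment(int(es))
        cfg = EpisodeConfig(duration=duration, environment=env, seed=int(es))
        log = run_episode(cfg, controller=controller_from_params(x))
        tuples.append(stage_tuple_from_log(log, stages, energy_model))
    return worst_of(tuples, stages)


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------

@dataclass
class PsoConfig:
    n_particles: int = 40
    n_iters: int = 100
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    v_clamp: float = 0.2  # fraction of each parameter range


@dataclass
class ParticleState:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_score: tuple[int, float]


def pso_optimize(objective, bounds: tuple[np.ndarray, np.ndarray],
                 seed: int, config: PsoConfig | None = None,
                 stages: tuple[StageSpec, ...] = DEFAULT_STAGES,
                 callback=None):
    """Particle swarm with lexicographic personal/global best comparison.

    ``objective(x)`` must return a ``(stage, value)`` tuple; plain
    scalar minimization is expressed as a single min-sense stage.
    Returns ``(best_position, best_score, history)`` where history is
    the best-so-far tuple per iteration.  Fully reproducible from the
    seed.
    """
    config = config or PsoConfig()
    lo, hi = bounds
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    rng = np.random.default_rng(seed)
    n, d = config.n_particles, len(lo)
    pos = lo + span * rng.random((n, d))
    vel = config.v_clamp * span * (2 * rng.random((n, d)) - 1)
    particles = []
    g_pos, g_score = None, None
    for i in range(n):
        score = objective(pos[i])
        particles.append(ParticleState(pos[i].copy(), vel[i].copy(),
                                       pos[i].copy(), score))
        if g_score is None or lexicographic_rank(score, g_score, stages) < 0:
            g_pos, g_score = pos[i].copy(), score
    history = [g_score]
    vmax = config.v_clamp * span
    for it in range(config.n_iters):
        for p in particles:
            r1 = rng.random(d)
            r2 = rng.random(d)
            p.velocity = (config.inertia * p.velocity
                          + config.cognitive * r1 * (p.best_position - p.position)
                          + config.social * r2 * (g_pos - p.position))
            np.clip(p.velocity, -vmax, vmax, out=p.velocity)
            p.position = p.position + p.velocity
            # reflect at the walls
            over = p.position > hi
            under = p.position < lo
            p.position[over] = 2 * hi[over] - p.position[over]
            p.position[under] = 2 * lo[under] - p.position[under]
            np.clip(p.position, lo, hi, out=p.position)
            p.velocity[over | under] *= -1
            score = objective(p.position)
            if lexicographic_rank(score, p.best_score, stages) < 0:
                p.best_position = p.position.copy()
                p.best_score = score
            if lexicographic_rank(score, g_score, stages) < 0:
                g_pos = p.position.copy()
                g_score = score
        history.append(g_score)
        if callback is not None:
            callback(it, g_pos, g_score)
    return g_pos, g_score, history
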