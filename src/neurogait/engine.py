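"""Episode orchestration: the 1 ms sense→control→actuate→integrate loop.

Per control step the engine: reads raw sensors from the plant and
muscles, pushes them through the reflex controller's delay lines and
interneuron/motoneuron stages (optionally blended with the feedforward
predictor network), clamps stimulations, advances the muscles with
Euler sub-steps, aggregates muscle and ligament torques, applies
external pushes and contact, advances the rigid-body state with RK4,
updates the gait state machine and logs everything.

Episodes are bitwise deterministic given (config, seed): the engine
itself draws no random numbers; randomness enters only through the
seeded environment generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import plant as _plant
from .muscle import DEFAULT_MUSCLES, MUSCLE_NAMES, MuscleBank
from .plant import Biped, interior_angles, interior_velocities
from .reflex import (GRF_THRESHOLD, KNEE_OVEREXT_THRESHOLD, LimbState,
                     ReflexController, SensorSample, StateMachine)

__all__ = [
    "EpisodeConfig",
    "Environment",
    "TrajectoryLog",
    "run_episode",
    "generate_slope_environment",
    "detect_events",
    "max_recoverable_push",
    "Push",
]

_STATE_CODE = {LimbState.ST: 0, LimbState.SW: 1, LimbState.STEND: 2}


@dataclass(frozen=True)
class Push:
    """Horizontal external force on the trunk COM."""

    onset: float  # [s]
    force: float  # [N], +x is the walking direction
    duration: float = 0.25  # [s]


@dataclass
class Environment:
    """Ground elevation profile, piecewise linear."""

    profile: np.ndarray  # (n, 2) of (x, y)
    max_slope: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=float)
        grades = np.abs(np.diff(p[:, 1]) / np.diff(p[:, 0]))
        if np.any(grades > self.max_slope + 1e-12):
            raise ValueError("profile exceeds the maximum slope")
        self.profile = p


def flat_environment() -> Environment:
    return Environment(np.array([[-1e4, 0.0], [1e4, 0.0]]))


def generate_slope_environment(seed: int, max_slope: float = 0.05,
                               n_structures: int = 4,
                               x_start: float = 2.0) -> Environment:
    """Randomized terrain of trapezoidal up/down structures.

    Lengths, slopes and spacings are drawn from a seeded generator;
    every gradient stays at or below ``max_slope`` (5% by default).
    Reproducible: the same seed yields the same profile.
    """
    rng = np.random.default_rng(seed)
    xs = [-1e3, x_start]
    ys = [0.0, 0.0]
    x = x_start
    y = 0.0
    for _ in range(n_structures):
        gap = rng.uniform(2.0, 6.0)
        ramp = rng.uniform(2.0, 5.0)
        slope = rng.uniform(0.2, 1.0) * max_slope
        plateau = rng.uniform(1.0, 3.0)
        x += gap; xs.append(x); ys.append(y)
        x += ramp; y += slope * ramp; xs.append(x); ys.append(y)
        x += plateau; xs.append(x); ys.append(y)
        x += ramp; y -= slope * ramp; xs.append(x); ys.append(y)
    xs.append(x + 1e3); ys.append(y)
    return Environment(np.column_stack([xs, ys]), max_slope, seed)


@dataclass
class EpisodeConfig:
    duration: float = 10.0
    dt: float = 1e-3
    muscle_substeps: int = 20
    forward_speed: float = 1.2
    leg_split: float = 0.12  # initial hip split [rad], left forward
    pitch: float = 0.06  # initial forward lean [rad]
    environment: Environment = field(default_factory=flat_environment)
    pushes: tuple[Push, ...] = ()
    gravity: float = _plant.GRAVITY
    muscles_enabled: bool = True
    log_neural: bool = True
    seed: int = 0


class TrajectoryLog:
    """Uniform-time record of one episode.

    Column blocks: generalized coordinates/velocities, interior joint
    torques (hip/knee/ankle x L/R), normalized per-foot GRF, per-muscle
    force/activation/stimulation/CE state, limb states, interneuron
    values, CPG clock phases and gait events.
    """

    def __init__(self, n_steps: int, n_path: int, dt: float):
        self.dt = dt
        self.times = np.arange(n_steps) * dt
        self.q = np.zeros((n_steps, 9))
        self.qd = np.zeros((n_steps, 9))
        self.joint_torques = np.zeros((n_steps, 6))
        self.knee_lig = np.zeros((n_steps, 2))
        self.grf = np.zeros((n_steps, 2))
        self.m_force = np.zeros((n_steps, 14))
        self.m_act = np.zeros((n_steps, 14))
        self.m_stim = np.zeros((n_steps, 14))
        self.m_lce = np.zeros((n_steps, 14))
        self.m_vce = np.zeros((n_steps, 14))
        self.limb_states = np.zeros((n_steps, 2), dtype=int)
        self.in_sen = np.zeros((n_steps, 2, n_path))
        self.cpg_phase = np.zeros((n_steps, 4))
        self.touchdowns: list[np.ndarray] = [np.empty(0), np.empty(0)]
        self.takeoffs: list[np.ndarray] = [np.empty(0), np.empty(0)]
        self.fell = False
        self.t_fall = math.nan
        self.distance = 0.0

    def trim(self, n: int) -> None:
        for name in ("times", "q", "qd", "joint_torques", "knee_lig", "grf",
                     "m_force", "m_act", "m_stim", "m_lce", "m_vce",
                     "limb_states", "in_sen", "cpg_phase"):
            setattr(self, name, getattr(self, name)[:n])

    @property
    def n_steps(self) -> int:
        return len(self.times)

    @property
    def in_sen_traces(self) -> np.ndarray:
        """(2, n_path, n_t) view used by the predictor extraction."""
        return np.transpose(self.in_sen, (1, 2, 0))

    def to_frame(self):
        """Tabular export (one row per control step)."""
        import pandas as pd
        cols = {"time": self.times,
                **{f"q{i}": self.q[:, i] for i in range(9)},
                **{f"qd{i}": self.qd[:, i] for i in range(9)},
                "grf_L": self.grf[:, 0], "grf_R": self.grf[:, 1],
                "state_L": self.limb_states[:, 0],
                "state_R": self.limb_states[:, 1]}
        for j, name in enumerate(("hip_L", "knee_L", "ankle_L",
                                  "hip_R", "knee_R", "ankle_R")):
            cols[f"tau_{name}"] = self.joint_torques[:, j]
        for i in range(14):
            side = "L" if i < 7 else "R"
            cols[f"F_{MUSCLE_NAMES[i % 7]}_{side}"] = self.m_force[:, i]
            cols[f"A_{MUSCLE_NAMES[i % 7]}_{side}"] = self.m_act[:, i]
        return pd.DataFrame(cols)


def detect_events(grf: np.ndarray, times: np.ndarray,
                  threshold: float = GRF_THRESHOLD,
                  debounce: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Touchdown/takeoff times of one foot from its normalized GRF trace.

    Touchdown is an upward crossing of the threshold, takeoff a downward
    one; events closer than the debounce window to the previous accepted
    event are discarded.
    """
    grf = np.asarray(grf, dtype=float)
    times = np.asarray(times, dtype=float)
    loaded = grf >= threshold
    flips = np.nonzero(np.diff(loaded.astype(int)))[0] + 1
    tds, tos = [], []
    t_last = -math.inf
    for i in flips:
        t = times[i]
        if t - t_last < debounce:
            continue
        (tds if loaded[i] else tos).append(t)
        t_last = t
    return np.asarray(tds), np.asarray(tos)


# ---------------------------------------------------------------------------
# episode loop
# ---------------------------------------------------------------------------

def run_episode(config: EpisodeConfig,
                controller: ReflexController | None = None,
                cpg=None,
                biped: Biped | None = None,
                muscles: MuscleBank | None = None) -> TrajectoryLog:
    """Run one walking episode and return its trajectory log.

    ``cpg`` is an optional predictor network; its ``combine`` hook blends
    the interneuron values before the motoneuron stage, and it is
    advanced each step with the gait events.  With every blend weight at
    1 the output is step-for-step identical to the pure-feedback run.
    """
    dt = config.dt
    biped = biped or Biped(ground=config.environment.profile,
                           gravity=config.gravity)
    biped.ground = config.environment.profile
    controller = controller or ReflexController(dt=dt)
    muscles = muscles or MuscleBank(DEFAULT_MUSCLES + DEFAULT_MUSCLES,
                                    n_sub=config.muscle_substeps)
    if cpg is not None:
        controller.cpg_hook = cpg.combine

    n_steps = int(round(config.duration / dt))
    log = TrajectoryLog(n_steps, controller.n_path, dt)
    state = biped.standing_state(forward_speed=config.forward_speed,
                                 leg_split=config.leg_split,
                                 pitch=config.pitch)
    # evaluate initial contact so the first GRF sample is consistent
    kin = biped.kinematics(state.q, state.qd)
    state.contact_forces, state.anchors = biped._contact_eval(kin, state.anchors)

    ang = interior_angles(state.q)
    l_mtu0 = _mtu_lengths(ang)
    muscles.reset(l_mtu0)
    sm = StateMachine()
    sm.states = [LimbState.ST, LimbState.ST]

    att = _attachment_table()
    fell = False
    step_count = n_steps
    for i in range(n_steps):
        t = i * dt
        grf = biped.foot_grf(state)
        ang = interior_angles(state.q)
        vel = interior_velocities(state.qd)
        pitch, pitch_rate = biped.trunk_pitch(state)
        knee_over = np.array([
            _knee_overextension(ang["knee"][s], vel["knee"][s]) for s in range(2)])
        sensors = SensorSample(
            m_force=muscles.norm_force.reshape(2, 7),
            m_length=muscles.norm_length.reshape(2, 7),
            knee_over=knee_over, grf=grf,
            pitch=pitch, pitch_rate=pitch_rate)
        sensors.validate()

        stim, in_sen = controller.step(sensors, sm.states)

        if config.muscles_enabled:
            l_mtu = _mtu_lengths(ang)
            muscles.step(l_mtu, stim.reshape(-1), dt)
            forces = muscles.force
        else:
            forces = np.zeros(14)

        lig = biped.ligament_interior_torques(state.q, state.qd)
        tau = {j: lig[j].copy() for j in ("hip", "knee", "ankle")}
        for m_idx, joint, sign, r0, phi_max in att:
            for s in range(2):
                phi = ang[joint][s]
                r = r0 if phi_max is None else r0 * math.cos(phi - phi_max)
                tau[joint][s] += sign * forces[s * 7 + m_idx] * r
        Q_joint = biped.joint_generalized_torques(tau)

        ext = []
        for push in config.pushes:
            if push.onset <= t < push.onset + push.duration:
                ext.append((0, np.array([push.force, 0.0])))

        # log before integrating (sample i describes time t)
        log.q[i] = state.q
        log.qd[i] = state.qd
        log.grf[i] = grf
        log.joint_torques[i] = np.array([tau["hip"][0], tau["knee"][0],
                                         tau["ankle"][0], tau["hip"][1],
                                         tau["knee"][1], tau["ankle"][1]])
        log.knee_lig[i] = lig["knee"]
        log.m_force[i] = forces
        log.m_act[i] = muscles.act
        log.m_stim[i] = stim.reshape(-1)
        log.m_lce[i] = muscles.l_ce
        log.m_vce[i] = muscles.v_ce
        log.limb_states[i] = [_STATE_CODE[s] for s in sm.states]
        if config.log_neural:
            log.in_sen[i] = in_sen
        if cpg is not None:
            log.cpg_phase[i] = cpg.phases()

        state = biped.step_dynamics(state, Q_joint, ext or None, dt)

        prev_states = list(sm.states)
        sm.update(biped.foot_grf(state), t + dt)
        if cpg is not None:
            events = {}
            for limb, side in enumerate("LR"):
                was_sw = prev_states[limb] == LimbState.SW
                is_sw = sm.states[limb] == LimbState.SW
                events[(side, "touchdown")] = was_sw and not is_sw
                events[(side, "takeoff")] = (not was_sw) and is_sw
            cpg.step(dt, events)

        if biped.has_fallen(state):
            fell = True
            log.fell = True
            log.t_fall = t + dt
            step_count = i + 1
            break

    log.trim(step_count)
    log.touchdowns = [np.asarray(sm.touchdowns[0]), np.asarray(sm.touchdowns[1])]
    log.takeoffs = [np.asarray(sm.takeoffs[0]), np.asarray(sm.takeoffs[1])]
    log.distance = float(log.q[-1, 0] - log.q[0, 0]) if step_count else 0.0
    return log


def _mtu_lengths(ang: dict[str, np.ndarray]) -> np.ndarray:
    """MTU lengths of all 14 muscles from interior joint angles (L then R)."""
    from .muscle import mtu_length
    out = np.empty(14)
    for s in range(2):
        angles = {j: float(ang[j][s]) for j in ("hip", "knee", "ankle")}
        for m, p in enumerate(DEFAULT_MUSCLES):
            out[s * 7 + m] = mtu_length(angles, p)
    return out


def _knee_overextension(phi: float, phi_dot: float,
                        threshold: float = KNEE_OVEREXT_THRESHOLD) -> float:
    """Type-2 sensor: proportional to the overshoot beyond the tolerated
    knee angle, active only while moving toward extension."""
    if phi > threshold and phi_dot > 0:
        return phi - threshold
    return 0.0


def _attachment_table():
    table = []
    for m_idx, p in enumerate(DEFAULT_MUSCLES):
        for a in p.attachments:
            table.append((m_idx, a.joint, a.sign, a.r0, a.phi_max))
    return tuple(table)


def max_recoverable_push(run_with_force, f_hi: float = 80.0,
                         tol: float = 1.0) -> float:
    """Largest push force (within ``tol`` newtons) the gait recovers from.

    ``run_with_force(f)`` must return True when the model stays upright
    after a push of ``f`` newtons.  Monotone bisection on [0, f_hi];
    returns 0 if even the smallest probe fails.
    """
    lo, hi = 0.0, f_hi
    if not run_with_force(lo):
        return 0.0
    if run_with_force(hi):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if run_with_force(mid):
            lo = mid
        else:
            hi = mid
    return lo
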