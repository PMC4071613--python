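"""Feedforward predictors: morphed oscillators and constant predictors.

The feedforward extension treats central pattern generators as
*predictors of the feedback signals*: each eligible reflex pathway gets
a predictor of its interneuron signal, and the motoneuron input becomes
the convex blend ``alpha * IN_sen + (1 - alpha) * IN_cpg``.

Two predictor families are implemented:

* the **morphed oscillator** (OSC), a phase oscillator whose output ``x``
  converges at rate ``gamma`` to an arbitrary 1-periodic differentiable
  shaping function ``g(theta)`` extracted from recorded gait cycles::

      theta' = omega
      x'     = gamma (g(theta) - x) + dg/dtheta * theta' + K

* the **constant predictor** (CST), the mean of the signal over the part
  of the cycle where the pathway is active.

Four phase clocks drive the network (left/right limb x
touchdown-/takeoff-synchronized).  Each clock is kept in lock with the
gait by (a) restarting its phase at its synchronization event and (b) a
slowing-down mechanism that engages after a fraction ``p`` (default 0.9)
of the period and guarantees the phase never exceeds 1 before the next
event::

      theta' = omega                 while t < p/omega
      theta' = c(t)                  afterwards,

with ``c(t) = omega * exp(-(omega/(1-p)) (t - p/omega))``; for p = 0.9
this is the closed form ``10 omega exp(-10 omega t - ln 10 + 9)``.  The
rate is continuous at the onset (``c(p/omega) = omega``) and the
remaining phase integral is exactly ``1 - p``.

Two low-dimensional supraspinal commands modulate the whole network: a
shared frequency ``omega`` for all four clocks and amplitude scalings
``mu_osc`` / ``mu_cst`` applied to the predictor outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .reflex import PathwaySpec

__all__ = [
    "ShapingFunction",
    "OscillatorState",
    "PhaseClock",
    "CombinationConfig",
    "CpgNetwork",
    "PRESETS",
    "extract_shaping_function",
    "constant_predictor",
    "oscillator_step",
    "phase_advance",
    "slowdown_rate",
    "phase_at",
    "combine_motoneurons",
    "apply_supraspinal",
    "build_cpg_network",
    "passive_reproduction",
]

DEFAULT_GAMMA = 100.0
DEFAULT_P = 0.9


# ---------------------------------------------------------------------------
# shaping functions
# ---------------------------------------------------------------------------

@dataclass
class ShapingFunction:
    """1-periodic cubic-spline shape ``g(theta)``, theta in [0, 1].

    Built from the pointwise mean of time-normalized signal cycles; the
    mean samples are clamped to [0, 1] (they approximate clamped
    interneuron activities) and closed periodically, so g(0) = g(1).
    """

    spline: CubicSpline
    n_cycles: int
    source: str = ""
    event: str = "touchdown"

    def __call__(self, theta):
        return self.spline(np.mod(theta, 1.0))

    def deriv(self, theta):
        return self.spline(np.mod(theta, 1.0), 1)

    @classmethod
    def from_samples(cls, mean_cycle: np.ndarray, n_cycles: int,
                     source: str = "", event: str = "touchdown"
                     ) -> "ShapingFunction":
        y = np.clip(np.asarray(mean_cycle, dtype=float), 0.0, 1.0)
        theta = np.linspace(0.0, 1.0, len(y) + 1)
        y_closed = np.concatenate([y, y[:1]])
        sp = CubicSpline(theta, y_closed, bc_type="periodic")
        return cls(sp, n_cycles, source, event)


def extract_shaping_function(signal: np.ndarray, times: np.ndarray,
                             event_times: np.ndarray, n_points: int = 200,
                             source: str = "", event: str = "touchdown"
                             ) -> ShapingFunction:
    """Extract the typical cycle shape of a periodic signal.

    The signal is cut at consecutive event times, each cycle is
    time-normalized to theta in [0, 1), the cycles are averaged
    pointwise and the mean is fitted with a periodic cubic spline.
    Requires at least two complete cycles and strictly increasing event
    times.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    ev = np.asarray(event_times, dtype=float)
    ev = ev[(ev >= times[0]) & (ev <= times[-1])]
    if len(ev) < 3:
        raise ValueError("need at least 2 complete cycles")
    if np.any(np.diff(ev) <= 0):
        raise ValueError("event times must be strictly increasing")
    theta_grid = np.arange(n_points) / n_points
    cycles = np.empty((len(ev) - 1, n_points))
    for i in range(len(ev) - 1):
        t0, t1 = ev[i], ev[i + 1]
        cycles[i] = np.interp(t0 + theta_grid * (t1 - t0), times, signal)
    mean = cycles.mean(axis=0)
    return ShapingFunction.from_samples(mean, len(cycles), source, event)


def constant_predictor(signal: np.ndarray, active_mask: np.ndarray) -> float:
    """Mean of the signal over the samples where the pathway is active."""
    mask = np.asarray(active_mask, dtype=bool)
    if not mask.any():
        raise ValueError("active-phase mask is empty")
    return float(np.asarray(signal, dtype=float)[mask].mean())


# ---------------------------------------------------------------------------
# phase dynamics
# ---------------------------------------------------------------------------

def slowdown_rate(t: float, omega: float, p: float = DEFAULT_P) -> float:
    """Phase rate c(t) of the slowing-down mechanism (t since last sync)."""
    return omega * math.exp(-(omega / (1.0 - p)) * (t - p / omega))


def phase_at(t: float, omega: float, p: float = DEFAULT_P) -> float:
    """Closed-form phase at time ``t`` since the last synchronization.

    Linear (``omega * t``) until the slowdown onset at ``t = p/omega``,
    then saturating toward (but never reaching) 1.
    """
    t_on = p / omega
    if t < t_on:
        return omega * t
    theta = p + (1.0 - p) * (1.0 - math.exp(-(omega / (1.0 - p)) * (t - t_on)))
    return min(theta, 1.0)  # guard against rounding at long waits


def phase_rate_at(t: float, omega: float, p: float = DEFAULT_P) -> float:
    return omega if t < p / omega else slowdown_rate(t, omega, p)


@dataclass
class OscillatorState:
    """Phase-clock plus one morphed-oscillator output channel."""

    theta: float = 0.0
    x: float = 0.0
    omega: float = 1.0
    gamma: float = DEFAULT_GAMMA
    coupling: float = 0.0  # the additive forcing K; 0 by default
    t_since: float = 0.0  # time since last synchronization event [s]
    p: float = DEFAULT_P


class PhaseClock:
    """One of the four event-synchronized phase clocks.

    Phase is the closed-form function of the time since the last
    synchronization event, so the invariant ``0 <= theta < 1`` between
    events holds exactly; the event resets time and phase (the formal
    reset rule fires whenever the event arrives after a full nominal
    period, i.e. the oscillator lags the gait).
    """

    def __init__(self, omega: float, p: float = DEFAULT_P):
        if omega <= 0:
            raise ValueError("omega must be positive")
        self.omega = omega
        self.p = p
        self.t_since = 0.0

    @property
    def theta(self) -> float:
        return phase_at(self.t_since, self.omega, self.p)

    @property
    def theta_dot(self) -> float:
        return phase_rate_at(self.t_since, self.omega, self.p)

    def advance(self, dt: float) -> None:
        self.t_since += dt

    def sync(self) -> None:
        self.t_since = 0.0

    def theta_between(self, tau: float) -> tuple[float, float]:
        """Phase and rate ``tau`` seconds into the current step."""
        t = self.t_since + tau
        return (phase_at(t, self.omega, self.p),
                phase_rate_at(t, self.omega, self.p))


def phase_advance(state: OscillatorState, sync_event: bool, dt: float
                  ) -> OscillatorState:
    """Advance the phase variable one step; reset on the sync event.

    The phase follows ``theta' = omega`` until ``p/omega`` after the last
    event, then the slowing-down rate; at the synchronization event the
    phase restarts at 0 (formally mandated whenever the event arrives
    later than one nominal period).
    """
    if sync_event:
        state.t_since = 0.0
        state.theta = 0.0
        return state
    state.t_since += dt
    state.theta = phase_at(state.t_since, state.omega, state.p)
    return state


def oscillator_step(state: OscillatorState, g: ShapingFunction | None,
                    dt: float) -> OscillatorState:
    """One RK4 step of the morphed-oscillator output ``x``.

    The phase is advanced with its exact closed form; the output relaxes
    toward the shaping function at rate ``gamma`` while the feedforward
    term ``dg/dtheta * theta'`` keeps it tracking on the limit cycle.
    """
    if g is None:
        raise ValueError("shaping function required")
    t0 = state.t_since
    om, p, gam, K = state.omega, state.p, state.gamma, state.coupling

    def f(tau, x):
        t = t0 + tau
        th = phase_at(t, om, p)
        thd = phase_rate_at(t, om, p)
        return gam * (float(g(th)) - x) + float(g.deriv(th)) * thd + K

    x = state.x
    k1 = f(0.0, x)
    k2 = f(dt / 2, x + dt / 2 * k1)
    k3 = f(dt / 2, x + dt / 2 * k2)
    k4 = f(dt, x + dt * k3)
    state.x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    state.t_since = t0 + dt
    state.theta = phase_at(state.t_since, om, p)
    return state


# ---------------------------------------------------------------------------
# combination with the feedback pathways
# ---------------------------------------------------------------------------

def combine_motoneurons(x_in_sen: np.ndarray, x_in_cpg: np.ndarray,
                        alpha: np.ndarray, G: np.ndarray, x0_mn: np.ndarray,
                        form: str = "blend") -> np.ndarray:
    """Motoneuron activities from the feedback/feedforward blend.

    ``form='blend'`` computes ``G (a*sen + (1-a)*cpg) + x0``;
    ``form='corrective'`` the algebraically identical
    ``G (cpg + a*(sen - cpg)) + x0`` (feedforward term plus corrective
    feedback difference).  Output clamped to [0, 1].
    """
    sen = np.asarray(x_in_sen, dtype=float)
    cpg = np.asarray(x_in_cpg, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if not (sen.shape == cpg.shape == a.shape):
        raise ValueError("dimension mismatch")
    if form == "blend":
        mix = a * sen + (1.0 - a) * cpg
    elif form == "corrective":
        mix = cpg + a * (sen - cpg)
    else:
        raise ValueError(f"unknown form {form!r}")
    G = np.atleast_2d(np.asarray(G, dtype=float))
    return np.clip(G @ mix + np.asarray(x0_mn, dtype=float), 0.0, 1.0)


@dataclass
class CombinationConfig:
    """Per-pathway predictor mode and blend weight.

    ``modes`` maps pathway name to 'fdb' (pure feedback), 'osc' or
    'cst'; unlisted pathways stay pure feedback with alpha = 1.
    ``mu_osc`` / ``mu_cst`` scale the predictor outputs, ``omega``
    overrides the network frequency (None = estimate from the recording).
    """

    modes: dict[str, str] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    mu_osc: float = 1.0
    mu_cst: float = 1.0
    omega: float | None = None

    def __post_init__(self) -> None:
        for name, a in self.alpha.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha[{name}] outside [0, 1]")
        if self.mu_osc <= 0 or self.mu_cst <= 0:
            raise ValueError("mu must be positive")


_ANKLE_PATHS = ("GAS<-GAS MFF ST", "SOL<-SOL MFF ST", "TA<-SOL MFF ST",
                "TA<-TA MLF CY")
_HIP_PATHS = ("GLU<-GLU MFF SW", "HAM<-HAM MFF SW", "HF<-HAM MLF SW",
              "HF<-HF MLF SW")

#: The five named feedforward/feedback model variants.  The alpha values
#: encode the published textual descriptions (which muscle groups carry
#: predictors, OSC vs CST, minimal-feedback construction); they are
#: documented configuration, not fitted constants.
PRESETS: dict[str, CombinationConfig] = {
    "3FBL_ankle": CombinationConfig(
        modes={n: "osc" for n in _ANKLE_PATHS},
        alpha={n: 0.1 for n in _ANKLE_PATHS}),
    "3FBL_hipA": CombinationConfig(
        modes={n: "osc" for n in _HIP_PATHS},
        alpha={n: 0.1 for n in _HIP_PATHS}),
    "3FBL_hipB": CombinationConfig(
        modes={"HF<-HAM MLF SW": "osc", "HF<-HF MLF SW": "osc"},
        alpha={"HF<-HAM MLF SW": 0.1, "HF<-HF MLF SW": 0.1}),
    "3FBL_biArt": CombinationConfig(
        modes={"HF<-HAM MLF SW": "osc"},
        alpha={"HF<-HAM MLF SW": 0.1}),
    # distal pathways replaced by constants, proximal ones by oscillators,
    # with the lowest alphas that keep the muscle-feedback activity at 35%
    "3FBL_min_fdb": CombinationConfig(
        modes={**{n: "cst" for n in _ANKLE_PATHS},
               **{n: "osc" for n in _HIP_PATHS}},
        alpha={**{n: 0.0 for n in _ANKLE_PATHS},
               "GLU<-GLU MFF SW": 0.5, "HAM<-HAM MFF SW": 0.5,
               "HF<-HAM MLF SW": 0.9, "HF<-HF MLF SW": 0.3,
               "VAS<-VAS MFF ST": 0.95}),
}


@dataclass
class _PathwayPredictor:
    mode: str  # 'fdb' | 'osc' | 'cst'
    alpha: float
    clock: int  # index into the 4 clocks (-1 for fdb/cst)
    shaping: ShapingFunction | None = None
    level: float = 0.0  # constant-predictor level
    x: float = 0.0  # oscillator output state


class CpgNetwork:
    """Predictor bank for both limbs, driven by four phase clocks.

    Clocks 0/1 are the left limb's touchdown-/takeoff-synchronized
    clocks, 2/3 the right limb's.  Pathways active during stance or the
    whole cycle bind to the touchdown clock, swing pathways to the
    takeoff clock.  All clocks share the supraspinal frequency
    ``omega``; predictor outputs are scaled by ``mu_osc`` / ``mu_cst``
    before combination.
    """

    CLOCKS = (("L", "touchdown"), ("L", "takeoff"),
              ("R", "touchdown"), ("R", "takeoff"))

    def __init__(self, pathways: list[PathwaySpec], omega: float,
                 gamma: float = DEFAULT_GAMMA, p: float = DEFAULT_P,
                 mu_osc: float = 1.0, mu_cst: float = 1.0):
        if omega <= 0:
            raise ValueError("omega must be positive")
        self.pathways = list(pathways)
        self.n_path = len(self.pathways)
        self.gamma = gamma
        self.p = p
        self.mu_osc = mu_osc
        self.mu_cst = mu_cst
        self.clocks = [PhaseClock(omega, p) for _ in range(4)]
        # per limb, per pathway
        self.predictors: list[list[_PathwayPredictor]] = [
            [_PathwayPredictor("fdb", 1.0, -1) for _ in self.pathways]
            for _ in range(2)]

    # -- configuration ---------------------------------------------------
    @property
    def omega(self) -> float:
        return self.clocks[0].omega

    def clock_index(self, limb: int, phase: str) -> int:
        kind = "takeoff" if phase == "swing" else "touchdown"
        return limb * 2 + (1 if kind == "takeoff" else 0)

    def bind(self, limb: int, path_idx: int, mode: str, alpha: float,
             shaping: ShapingFunction | None = None, level: float = 0.0
             ) -> None:
        phase = self.pathways[path_idx].phase
        clock = self.clock_index(limb, phase) if mode == "osc" else -1
        if mode == "osc":
            if shaping is None:
                raise ValueError("osc predictor requires a shaping function")
            if shaping.event != self.CLOCKS[clock][1]:
                raise ValueError(
                    f"pathway {self.pathways[path_idx].name!r} is "
                    f"{phase}-phase and must bind to the "
                    f"{self.CLOCKS[clock][1]}-synchronized clock")
        pred = _PathwayPredictor(mode, alpha, clock, shaping, level)
        if mode == "osc":
            pred.x = float(shaping(0.0))
        self.predictors[limb][path_idx] = pred

    @property
    def alpha(self) -> np.ndarray:
        return np.array([[p.alpha for p in side] for side in self.predictors])

    def n_oscillators(self, limb: int | None = None) -> int:
        sides = range(2) if limb is None else [limb]
        return sum(1 for s in sides for p in self.predictors[s]
                   if p.mode == "osc")

    # -- dynamics ---------------------------------------------------------
    def step(self, dt: float, events: dict[tuple[str, str], bool] | None = None
             ) -> None:
        """Advance clocks and oscillator outputs one control step.

        ``events`` flags synchronization events by (side, kind), e.g.
        ``{("L", "touchdown"): True}``.
        """
        events = events or {}
        for ci, key in enumerate(self.CLOCKS):
            if events.get(key, False):
                self.clocks[ci].sync()
        for side in self.predictors:
            for pred in side:
                if pred.mode != "osc":
                    continue
                clock = self.clocks[pred.clock]
                st = OscillatorState(theta=clock.theta, x=pred.x,
                                     omega=clock.omega, gamma=self.gamma,
                                     t_since=clock.t_since, p=self.p)
                oscillator_step(st, pred.shaping, dt)
                pred.x = st.x
        for clock in self.clocks:
            clock.advance(dt)

    def outputs(self) -> np.ndarray:
        """X_in_cpg, shape (2, n_path): predictor outputs after amplitude
        modulation; components of unmodeled pathways are 0."""
        out = np.zeros((2, self.n_path))
        for limb in range(2):
            for k, pred in enumerate(self.predictors[limb]):
                if pred.mode == "osc":
                    out[limb, k] = self.mu_osc * min(1.0, max(0.0, pred.x))
                elif pred.mode == "cst":
                    out[limb, k] = self.mu_cst * min(1.0, max(0.0, pred.level))
        return out

    def combine(self, in_sen: np.ndarray) -> np.ndarray:
        """Blend sensory and predictor interneuron values per pathway."""
        a = self.alpha
        return a * in_sen + (1.0 - a) * self.outputs()

    def phases(self) -> np.ndarray:
        return np.array([c.theta for c in self.clocks])


def apply_supraspinal(network: CpgNetwork, mu_osc: float | None = None,
                      mu_cst: float | None = None, omega: float | None = None
                      ) -> CpgNetwork:
    """Set the supraspinal commands: shared clock frequency and predictor
    amplitude scalings.  All four clocks share omega."""
    if mu_osc is not None:
        if mu_osc <= 0:
            raise ValueError("mu_osc must be positive")
        network.mu_osc = mu_osc
    if mu_cst is not None:
        if mu_cst <= 0:
            raise ValueError("mu_cst must be positive")
        network.mu_cst = mu_cst
    if omega is not None:
        if omega <= 0:
            raise ValueError("omega must be positive")
        for c in network.clocks:
            c.omega = omega
    return network


# ---------------------------------------------------------------------------
# network construction from a recorded gait
# ---------------------------------------------------------------------------

def _phase_mask(times: np.ndarray, phase: str, touchdowns: np.ndarray,
                takeoffs: np.ndarray) -> np.ndarray:
    """Boolean mask of the samples during which a pathway phase is active."""
    if phase == "cycle":
        return np.ones_like(times, dtype=bool)
    stance = np.zeros_like(times, dtype=bool)
    for td in touchdowns:
        nxt = takeoffs[takeoffs > td]
        t_end = nxt[0] if len(nxt) else times[-1]
        stance |= (times >= td) & (times < t_end)
    if phase in ("stance", "stance_end"):
        return stance
    return ~stance


def build_cpg_network(pathways: list[PathwaySpec], config: CombinationConfig,
                      recorded, muscle_sensors_only: bool = True
                      ) -> CpgNetwork:
    """Build the predictor bank from a recorded (or synthetic) gait.

    ``recorded`` must expose ``times`` (s), per-limb pathway signal
    traces ``in_sen`` (2, n_path, n_t) and per-limb event arrays
    ``touchdowns[limb]`` / ``takeoffs[limb]``.  Shaping functions are
    extracted per pathway with the segmentation event dictated by its
    phase (takeoff for swing pathways, touchdown otherwise); the network
    frequency defaults to the recording's mean cycle rate.

    Only muscle-sensor pathways (nine per limb) receive predictors
    unless ``muscle_sensors_only`` is False and the config lists others.
    """
    times = np.asarray(recorded.times, dtype=float)
    cycles = np.diff(np.asarray(recorded.touchdowns[0], dtype=float))
    if config.omega is not None:
        omega = config.omega
    else:
        if len(cycles) == 0:
            raise ValueError("recording has no complete cycles")
        omega = 1.0 / float(cycles.mean())
    net = CpgNetwork(pathways, omega, mu_osc=config.mu_osc,
                     mu_cst=config.mu_cst)
    for limb in range(2):
        td = np.asarray(recorded.touchdowns[limb], dtype=float)
        to = np.asarray(recorded.takeoffs[limb], dtype=float)
        for k, p in enumerate(pathways):
            mode = config.modes.get(p.name, "fdb")
            if mode == "fdb":
                continue
            if muscle_sensors_only and not p.is_muscle_sensor:
                raise ValueError(
                    f"pathway {p.name!r} is not CPG-eligible by default")
            sig = np.asarray(recorded.in_sen[limb][k], dtype=float)
            alpha = config.alpha.get(p.name, 1.0)
            if mode == "cst":
                mask = _phase_mask(times, p.phase, td, to)
                net.bind(limb, k, "cst", alpha,
                         level=constant_predictor(sig, mask))
            else:
                ev_kind = "takeoff" if p.phase == "swing" else "touchdown"
                ev = to if ev_kind == "takeoff" else td
                sf = extract_shaping_function(sig, times, ev,
                                              source=p.name, event=ev_kind)
                net.bind(limb, k, "osc", alpha, shaping=sf)
    return net


def passive_reproduction(network: CpgNetwork, times: np.ndarray,
                         touchdowns, takeoffs, dt: float | None = None
                         ) -> np.ndarray:
    """Run the oscillators passively against given event trains.

    No action on the muscles: the clocks are synchronized by the events
    and the raw predictor outputs are recorded.  Returns an array
    (2, n_path, n_t) of reproduced interneuron signals (zero for
    pathways without an OSC predictor).
    """
    times = np.asarray(times, dtype=float)
    if dt is None:
        dt = float(times[1] - times[0])
    out = np.zeros((2, network.n_path, len(times)))
    ev_sets = {}
    for limb, side in enumerate("LR"):
        ev_sets[(side, "touchdown")] = np.asarray(touchdowns[limb], dtype=float)
        ev_sets[(side, "takeoff")] = np.asarray(takeoffs[limb], dtype=float)
    for i, t in enumerate(times):
        events = {key: bool(np.any((ev >= t) & (ev < t + dt)))
                  for key, ev in ev_sets.items()}
        network.step(dt, events)
        snap = network.outputs()
        out[:, :, i] = snap
    return out
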