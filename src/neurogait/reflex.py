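"""Reflex control network: sensors, delays, interneurons, motoneurons.

The controller maps delayed sensor signals to muscle stimulations in
three affine-plus-clamp stages (sensory interneurons, motoneurons,
stimulation), gated by a per-limb gait state machine.

Four sensor families feed the network: muscle force (Golgi tendon, type
1b) and muscle length (spindle, type 1a) signals normalized by F_max and
l_opt; a knee overextension-prevention signal (type 2); the per-foot
ground load normalized by body weight (type 3); and the trunk pitch /
pitch rate used by proportional-derivative balance pathways (type 4).

Transmission delays model nerve conduction: 2.5 ms for hip-muscle and
trunk sensors and hip motoneurons, 5 ms for knee-level signals, 10 ms
for ankle-level and ground signals; each applies twice per loop
(sensor→interneuron and motoneuron→muscle).  On the 1 ms control grid
the 2.5 ms delay rounds up to 3 ms.

Limb states: ST (stance), SW (swing), STend (double support finishing
stance).  A limb with normalized ground load below 0.1 is in swing; a
loaded limb whose contralateral limb has just touched down enters STend
and stays there until its own takeoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .muscle import MUSCLE_NAMES

__all__ = [
    "LimbState",
    "PathwaySpec",
    "SensorSample",
    "DelayLine",
    "StateMachine",
    "ReflexController",
    "build_default_pathways",
    "update_limb_state",
    "interneuron_update",
    "motoneuron_update",
    "stimulation_clamp",
    "trunk_balance_signal",
    "DEFAULT_BASAL",
    "GRF_THRESHOLD",
    "delay_steps",
]

GRF_THRESHOLD = 0.1

#: anatomical delay groups [s]
DELAY_HIP = 2.5e-3
DELAY_KNEE = 5.0e-3
DELAY_ANKLE = 10.0e-3

_MUSCLE_DELAY = {"GLU": DELAY_HIP, "HF": DELAY_HIP, "HAM": DELAY_HIP,
                 "VAS": DELAY_KNEE, "SOL": DELAY_ANKLE, "TA": DELAY_ANKLE,
                 "GAS": DELAY_ANKLE}

_MIDX = {m: i for i, m in enumerate(MUSCLE_NAMES)}


def delay_steps(delay: float, dt: float) -> int:
    """Delay in whole control steps, nearest-half-up."""
    return max(1, int(math.floor(delay / dt + 0.5)))


class LimbState(Enum):
    ST = "ST"
    SW = "SW"
    STEND = "STend"


@dataclass(frozen=True)
class PathwaySpec:
    """One sensory-interneuron pathway (one limb's copy).

    ``sign`` is the polarity of the interneuron's action on its target
    motoneuron; the interneuron value itself is clamped to [0, 1].
    ``l_off`` applies to muscle-length (1a) pathways only: the signal is
    ``max(0, l_CE/l_opt − l_off)``.
    """

    name: str
    sensor_type: str  # '1a' | '1b' | '2' | '3' | '4' | '3+4'
    source: str  # muscle name | 'iFoot' | 'cFoot' | 'Trunk' | 'KNEE'
    target: str  # muscle name
    phase: str  # 'stance' | 'swing' | 'stance_end' | 'cycle'
    sign: int
    gain: float
    offset: float = 0.0
    l_off: float = 0.0
    kd: float = 0.0  # derivative gain, PD (type 4) pathways only

    @property
    def is_muscle_sensor(self) -> bool:
        return self.sensor_type in ("1a", "1b")


def build_default_pathways() -> list[PathwaySpec]:
    """The 15 reflex pathways of one limb.

    Nine are muscle-sensor pathways (six force, three length); the
    remainder are balance (PD on trunk pitch, load-weighted), the
    contralateral-load VAS inhibition during double support, the
    swing-phase trunk-lean drive of HF and the knee
    overextension-prevention pathway.  Gains and offsets are starting
    values; they form the optimizer's search space.
    """
    P = PathwaySpec
    return [
        P("GAS<-GAS MFF ST", "1b", "GAS", "GAS", "stance", +1, 1.10),
        P("GLU<-GLU MFF SW", "1b", "GLU", "GLU", "swing", +1, 0.40),
        P("HAM<-HAM MFF SW", "1b", "HAM", "HAM", "swing", +1, 0.65),
        P("SOL<-SOL MFF ST", "1b", "SOL", "SOL", "stance", +1, 1.20),
        P("TA<-SOL MFF ST", "1b", "SOL", "TA", "stance", -1, 0.60),
        P("VAS<-VAS MFF ST", "1b", "VAS", "VAS", "stance", +1, 1.15),
        P("TA<-TA MLF CY", "1a", "TA", "TA", "cycle", +1, 1.10, l_off=0.71),
        P("HF<-HAM MLF SW", "1a", "HAM", "HF", "swing", -1, 0.65, l_off=0.85),
        P("HF<-HF MLF SW", "1a", "HF", "HF", "swing", -1, 0.35, l_off=0.65),
        P("HF<-GSIF ST", "3+4", "iFoot+Trunk", "HF", "stance", -1, 1.50, kd=0.25),
        P("HAM<-GSIF ST", "3+4", "iFoot+Trunk", "HAM", "stance", +1, 1.50, kd=0.25),
        P("GLU<-GSIF ST", "3+4", "iFoot+Trunk", "GLU", "stance", +1, 1.50, kd=0.25),
        P("VAS<-GCF STend", "3", "cFoot", "VAS", "stance_end", -1, 2.00),
        P("HF<-TLF SW", "4", "Trunk", "HF", "swing", +1, 0.50),
        P("VAS<-KNEE OPF", "2", "KNEE", "VAS", "cycle", -1, 2.00),
    ]


#: basal motoneuron activities, indexed like MUSCLE_NAMES
DEFAULT_BASAL = {"GLU": 0.05, "HF": 0.05, "VAS": 0.09, "SOL": 0.01,
                 "TA": 0.01, "HAM": 0.05, "GAS": 0.01}

#: trunk reference pitch for the balance pathways [rad], forward-positive
DEFAULT_THETA_REF = math.radians(6.0)

#: knee overextension sensor threshold [rad], interior angle
KNEE_OVEREXT_THRESHOLD = math.radians(170.0)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def interneuron_update(W: np.ndarray, delayed_sensors: np.ndarray,
                       x0: np.ndarray | float = 0.0) -> np.ndarray:
    """Affine map of delayed sensor activities, clamped to [0, 1]."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    x = np.asarray(delayed_sensors, dtype=float)
    if W.shape[1] != x.shape[0]:
        raise ValueError("weight/sensor dimension mismatch")
    return np.clip(W @ x + x0, 0.0, 1.0)


def motoneuron_update(G: np.ndarray, x_in: np.ndarray,
                      x0_mn: np.ndarray) -> np.ndarray:
    """Gated sum of interneuron activities plus basal activity, in [0, 1].

    ``G`` is the (possibly signed) gate matrix resolved for the current
    limb-state pair; rows are motoneurons, columns interneurons.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    x = np.asarray(x_in, dtype=float)
    if G.shape[1] != x.shape[0]:
        raise ValueError("gate/interneuron dimension mismatch")
    return np.clip(G @ x + np.asarray(x0_mn, dtype=float), 0.0, 1.0)


def stimulation_clamp(x_mn) -> np.ndarray:
    """Muscle stimulation: delayed motoneuron output with a 0.01 tone floor."""
    return np.clip(np.asarray(x_mn, dtype=float), 0.01, 1.0)


def trunk_balance_signal(pitch: float, pitch_rate: float, theta_ref: float,
                         kp: float, kd: float, grf: float) -> dict[str, float]:
    """Load-weighted PD balance contributions for the stance-leg muscles.

    Forward lean (pitch above the reference) excites the hip extensors
    GLU and HAM and inhibits the flexor HF; the whole correction is
    weighted by the ipsilateral normalized foot load, so an unloaded
    limb receives no correction.
    """
    pd = max(0.0, kp * (pitch - theta_ref) + kd * pitch_rate)
    v = min(1.0, max(0.0, grf) * pd)
    return {"GLU": v, "HAM": v, "HF": -v}


def update_limb_state(grf: float, contra_state: LimbState,
                      prev_state: LimbState,
                      contra_prev_state: LimbState | None = None) -> LimbState:
    """Single-limb state transition rule.

    Below the 0.1 load threshold the limb is in swing.  A loaded limb
    enters finishing stance (STend) when the contralateral limb has just
    touched down (SW -> ST) and remains there until its own takeoff;
    otherwise it is in stance.
    """
    if grf < GRF_THRESHOLD:
        return LimbState.SW
    contra_landed = (contra_prev_state == LimbState.SW
                     and contra_state != LimbState.SW)
    if contra_landed:
        return LimbState.STEND
    if prev_state == LimbState.STEND:
        return LimbState.STEND
    return LimbState.ST


def phase_active(phase: str, state: LimbState) -> bool:
    if phase == "cycle":
        return True
    if phase == "stance":
        return state in (LimbState.ST, LimbState.STEND)
    if phase == "stance_end":
        return state == LimbState.STEND
    if phase == "swing":
        return state == LimbState.SW
    raise ValueError(f"unknown phase {phase!r}")


class StateMachine:
    """Both limbs' gait states plus touchdown/takeoff event logs."""

    def __init__(self, debounce: float = 0.02):
        self.states = [LimbState.ST, LimbState.ST]
        self.debounce = debounce
        self.touchdowns: list[list[float]] = [[], []]
        self.takeoffs: list[list[float]] = [[], []]
        self._last_event_t = [-math.inf, -math.inf]

    def update(self, grf: np.ndarray, t: float) -> list[LimbState]:
        prev = list(self.states)
        new = [
            update_limb_state(float(grf[0]), prev[1], prev[0], prev[1]),
            update_limb_state(float(grf[1]), prev[0], prev[1], prev[0]),
        ]
        # re-resolve STend against the *new* contralateral states so a
        # simultaneous contralateral touchdown is seen this step
        new = [
            update_limb_state(float(grf[0]), new[1], prev[0], prev[1]),
            update_limb_state(float(grf[1]), new[0], prev[1], prev[0]),
        ]
        for i in range(2):
            was_sw = prev[i] == LimbState.SW
            is_sw = new[i] == LimbState.SW
            if was_sw != is_sw and t - self._last_event_t[i] >= self.debounce:
                (self.touchdowns if was_sw else self.takeoffs)[i].append(t)
                self._last_event_t[i] = t
        self.states = new
        return new


# ---------------------------------------------------------------------------
# delays
# ---------------------------------------------------------------------------

class DelayLine:
    """Ring buffer implementing a pure transmission delay.

    Exact for delays that are whole multiples of the step; pre-filled
    with the first pushed sample.  ``lags`` may be a scalar step count or
    a per-component array of step counts.
    """

    def __init__(self, dim: int, max_steps: int):
        self.dim = dim
        self.size = max_steps + 1
        self.buf = np.zeros((self.size, dim))
        self.head = 0
        self._primed = False

    def push(self, x) -> None:
        x = np.asarray(x, dtype=float)
        if not self._primed:
            self.buf[:] = x
            self._primed = True
        self.head = (self.head + 1) % self.size
        self.buf[self.head] = x

    def read(self, lags) -> np.ndarray:
        if np.isscalar(lags):
            return self.buf[(self.head - int(lags)) % self.size].copy()
        lags = np.asarray(lags, dtype=int)
        idx = (self.head - lags) % self.size
        return self.buf[idx, np.arange(self.dim)]


# ---------------------------------------------------------------------------
# full controller
# ---------------------------------------------------------------------------

@dataclass
class SensorSample:
    """Raw (undelayed) sensor snapshot for one control step."""

    m_force: np.ndarray  # (2, 7) F_m/F_max per limb and muscle
    m_length: np.ndarray  # (2, 7) l_CE/l_opt
    knee_over: np.ndarray  # (2,) overextension signal [rad]
    grf: np.ndarray  # (2,) normalized foot load
    pitch: float  # forward-positive trunk pitch [rad]
    pitch_rate: float

    def validate(self) -> None:
        for arr in (self.m_force, self.m_length, self.knee_over, self.grf):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite sensor sample")
        if np.any(self.grf < 0):
            raise ValueError("GRF must be nonnegative")


class ReflexController:
    """The feedback-only walking controller (two mirrored limbs).

    Per step: raw sensors are pushed into delay lines, each pathway's
    interneuron value is computed from its delayed inputs, gated by the
    limb state, summed onto its target motoneuron with its polarity,
    clamped, delayed again, and clamped to the stimulation interval
    [0.01, 1].

    ``cpg_hook``, if set, is called with the per-limb interneuron values
    and must return the blended values actually fed to the motoneurons
    (used by the feedforward extension).
    """

    def __init__(self,
                 pathways: list[PathwaySpec] | None = None,
                 basal: dict[str, float] | None = None,
                 theta_ref: float = DEFAULT_THETA_REF,
                 dt: float = 1e-3):
        self.pathways = list(pathways) if pathways is not None \
            else build_default_pathways()
        basal = dict(basal or DEFAULT_BASAL)
        self.x0 = np.array([basal[m] for m in MUSCLE_NAMES])
        self.theta_ref = theta_ref
        self.dt = dt
        self.n_path = len(self.pathways)
        self.cpg_hook = None

        max_steps = delay_steps(DELAY_ANKLE, dt)
        self._mf = DelayLine(14, max_steps)
        self._ml = DelayLine(14, max_steps)
        self._knee = DelayLine(2, max_steps)
        self._grf = DelayLine(2, max_steps)
        self._trunk = DelayLine(2, max_steps)
        self._mn = DelayLine(14, max_steps)

        mlag = np.array([delay_steps(_MUSCLE_DELAY[m], dt) for m in MUSCLE_NAMES])
        self._mlag = np.concatenate([mlag, mlag])
        self._knee_lag = delay_steps(DELAY_KNEE, dt)
        self._grf_lag = delay_steps(DELAY_ANKLE, dt)
        self._trunk_lag = delay_steps(DELAY_HIP, dt)

    # -- interneuron layer ---------------------------------------------
    def interneuron_values(self, limb: int, mf: np.ndarray, ml: np.ndarray,
                           knee: np.ndarray, grf: np.ndarray,
                           pitch: float, pitch_rate: float) -> np.ndarray:
        """Clamped interneuron value of every pathway of one limb."""
        contra = 1 - limb
        v = np.empty(self.n_path)
        for k, p in enumerate(self.pathways):
            if p.sensor_type == "1b":
                s = mf[limb * 7 + _MIDX[p.source]]
                val = p.gain * s + p.offset
            elif p.sensor_type == "1a":
                s = max(0.0, ml[limb * 7 + _MIDX[p.source]] - p.l_off)
                val = p.gain * s + p.offset
            elif p.sensor_type == "2":
                val = p.gain * knee[limb]
            elif p.sensor_type == "3":  # contralateral foot load
                val = p.gain * grf[contra]
            elif p.sensor_type == "4":  # trunk lean (swing drive)
                val = p.gain * (pitch - self.theta_ref)
            elif p.sensor_type == "3+4":  # load-weighted balance PD
                pd = p.gain * (pitch - self.theta_ref) + p.kd * pitch_rate
                val = max(0.0, grf[limb]) * max(0.0, pd)
            else:
                raise ValueError(f"unknown sensor type {p.sensor_type!r}")
            v[k] = min(1.0, max(0.0, val))
        return v

    def motoneurons(self, values: np.ndarray, state: LimbState) -> np.ndarray:
        """Gate pathway values by limb state and sum onto the 7 motoneurons."""
        x = self.x0.copy()
        for k, p in enumerate(self.pathways):
            if phase_active(p.phase, state):
                x[_MIDX[p.target]] += p.sign * values[k]
        return np.clip(x, 0.0, 1.0)

    # -- one control step ------------------------------------------------
    def step(self, sensors: SensorSample, limb_states: list[LimbState]
             ) -> tuple[np.ndarray, np.ndarray]:
        """Advance the network one step.

        Returns ``(stim, in_sen)``: muscle stimulations (2, 7) and the
        raw interneuron values (2, n_path) before any feedforward blend.
        """
        self._mf.push(sensors.m_force.reshape(-1))
        self._ml.push(sensors.m_length.reshape(-1))
        self._knee.push(sensors.knee_over)
        self._grf.push(sensors.grf)
        self._trunk.push([sensors.pitch, sensors.pitch_rate])

        mf = self._mf.read(self._mlag)
        ml = self._ml.read(self._mlag)
        knee = self._knee.read(self._knee_lag)
        grf = self._grf.read(self._grf_lag)
        pitch, pitch_rate = self._trunk.read(self._trunk_lag)

        in_sen = np.stack([
            self.interneuron_values(0, mf, ml, knee, grf, pitch, pitch_rate),
            self.interneuron_values(1, mf, ml, knee, grf, pitch, pitch_rate),
        ])
        blended = in_sen if self.cpg_hook is None else self.cpg_hook(in_sen)
        mn = np.stack([
            self.motoneurons(blended[0], limb_states[0]),
            self.motoneurons(blended[1], limb_states[1]),
        ])
        self._mn.push(mn.reshape(-1))
        mn_delayed = self._mn.read(self._mlag)
        stim = stimulation_clamp(mn_delayed).reshape(2, 7)
        return stim, in_sen
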