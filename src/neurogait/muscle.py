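"""Hill-type muscle–tendon units (MTU).

A muscle–tendon unit consists of an active contractile element (CE) with
two passive parallel buffers (PE, which resists over-stretch, and BE,
which prevents the fiber from collapsing) in series with a tendon (series
elasticity, SE).  The net force transmitted to the skeleton is the tendon
force, ``F_m = F_SE = F_CE + F_PE − F_BE``.

Sign convention: ``v_CE > 0`` means the contractile element is
*lengthening* (eccentric contraction).  All lengths are in metres, forces
in newtons, velocities in m/s unless noted otherwise.

Shape functions follow the classic forms of the Hill-muscle literature:
a cubic-exponential bell for the force–length relation, a hyperbolic
force–velocity relation (concentric) with an eccentric branch saturating
at ``N`` times the isometric force, and quadratic-over-tolerance curves
for the passive elements.  The constants (w = 0.56, c = ln 0.05, N = 1.5,
K = 5, eps_ref = 0.04) are exposed per muscle and overridable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointAttachment",
    "MTUParams",
    "MTUState",
    "MuscleBank",
    "DEFAULT_MUSCLES",
    "MUSCLE_NAMES",
    "activation_step",
    "force_length",
    "force_velocity",
    "inverse_force_velocity",
    "mtu_force",
    "moment_arm",
    "mtu_length",
    "vce_from_equilibrium",
]

#: First-order excitation–contraction coupling rate constant [1/s].
TAU_ACT = 100.0

#: Stimulation floor modelling muscle tone.
STIM_MIN = 0.01


@dataclass(frozen=True)
class JointAttachment:
    """Geometry of one muscle–joint attachment.

    ``sign`` fixes the action of the muscle in interior-angle coordinates:
    the torque contributed is ``sign * F_m * r(phi)`` and, by virtual work,
    the MTU length changes as ``dl/dphi = −sign * r(phi)``.

    ``phi_max`` is the interior angle of maximal moment arm for knee and
    ankle attachments (``r = r0·cos(phi − phi_max)``); hip attachments
    have a constant moment arm (``phi_max is None``).
    """

    joint: str  # "hip" | "knee" | "ankle"
    r0: float  # peak moment arm [m]
    phi_max: float | None  # [rad]; None => constant (hip) arm
    phi_ref: float  # reference interior angle [rad]
    sign: int  # +1 / −1, see class docstring
    #: pennation-like attenuation of the fiber-length excursion: the CE
    #: sees rho * the joint excursion while the tendon acts at the full
    #: anatomical arm (convention of the underlying muscle model)
    rho: float = 1.0


@dataclass(frozen=True)
class MTUParams:
    name: str
    f_max: float  # maximum isometric force [N]
    l_opt: float  # optimal CE length [m]
    l_slack: float  # tendon slack length [m]
    v_max: float  # maximum shortening velocity [l_opt/s]
    attachments: tuple[JointAttachment, ...]
    # force–length bell
    w: float = 0.56
    c: float = math.log(0.05)
    # force–velocity hyperbola
    fv_n: float = 1.5
    fv_k: float = 5.0
    # tendon strain tolerance
    eps_ref: float = 0.04

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ValueError(f"{self.name}: f_max, l_opt and v_max must be positive")
        if not self.attachments:
            raise ValueError(f"{self.name}: at least one joint attachment required")
        for a in self.attachments:
            if a.r0 <= 0:
                raise ValueError(f"{self.name}: moment arm r0 must be positive")


@dataclass
class MTUState:
    l_ce: float
    v_ce: float = 0.0
    activation: float = 0.0
    stimulation: float = STIM_MIN
    f_ce: float = 0.0
    f_se: float = 0.0
    f_pe: float = 0.0
    f_be: float = 0.0

    @property
    def f_m(self) -> float:
        """Net MTU force; the tendon transmits it."""
        return self.f_se


def _deg(x: float) -> float:
    return math.radians(x)


def _default_table() -> tuple[MTUParams, ...]:
    """The seven muscles of the planar model.

    Attachment geometry (r0, phi_max, phi_ref) is the model's published
    joint table; F_max/l_opt/l_slack/v_max are the standard values of the
    reflex-walking literature (the model source does not print them) and
    are fully overridable.
    """
    A = JointAttachment
    return (
        MTUParams("GLU", 1500.0, 0.11, 0.13, 12.0,
                  (A("hip", 0.10, None, _deg(150), +1, rho=0.5),)),
        MTUParams("HF", 2000.0, 0.11, 0.10, 12.0,
                  (A("hip", 0.10, None, _deg(180), -1, rho=0.5),)),
        MTUParams("VAS", 6000.0, 0.08, 0.23, 12.0,
                  (A("knee", 0.06, _deg(165), _deg(125), +1, rho=0.6),)),
        MTUParams("SOL", 4000.0, 0.04, 0.26, 6.0,
                  (A("ankle", 0.05, _deg(110), _deg(80), -1, rho=0.5),)),
        MTUParams("TA", 800.0, 0.06, 0.24, 12.0,
                  (A("ankle", 0.04, _deg(80), _deg(110), +1, rho=0.7),)),
        MTUParams("HAM", 3000.0, 0.10, 0.31, 12.0,
                  (A("hip", 0.08, None, _deg(155), +1, rho=0.7),
                   A("knee", 0.08, _deg(180), _deg(180), -1, rho=0.7))),
        MTUParams("GAS", 1500.0, 0.05, 0.40, 12.0,
                  (A("ankle", 0.05, _deg(110), _deg(80), -1, rho=0.7),
                   A("knee", 0.05, _deg(140), _deg(165), -1, rho=0.7))),
    )


DEFAULT_MUSCLES: tuple[MTUParams, ...] = _default_table()
MUSCLE_NAMES: tuple[str, ...] = tuple(p.name for p in DEFAULT_MUSCLES)


# ---------------------------------------------------------------------------
# scalar relations
# ---------------------------------------------------------------------------

def activation_step(a: float, x_mtu: float, dt: float, tau: float = TAU_ACT) -> float:
    """Advance the excitation–contraction ODE ``dA/dt = tau (X − A)`` one step.

    Integrated exactly (the ODE is linear with constant input over the
    step); the result is clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_new = x_mtu + (a - x_mtu) * math.exp(-tau * dt)
    return min(1.0, max(0.0, a_new))


def force_length(l_ce, p: MTUParams):
    """Bell-shaped force–length relation, normalized: f_l(l_opt) = 1."""
    x = np.abs((np.asarray(l_ce, dtype=float) - p.l_opt) / (p.l_opt * p.w))
    return np.exp(p.c * x ** 3)


def force_velocity(v_ce, p: MTUParams):
    """Force–velocity relation; ``v_ce`` in m/s, lengthening positive.

    Concentric branch vanishes at the maximum shortening velocity;
    eccentric branch rises from 1 toward the saturation ``fv_n``.
    """
    v = np.asarray(v_ce, dtype=float) / p.l_opt  # [l_opt/s]
    vm, n, k = p.v_max, p.fv_n, p.fv_k
    short = (vm + v) / (vm - k * v)
    lengthen = n + (n - 1.0) * (v - vm) / (7.56 * k * v + vm)
    out = np.where(v < 0.0, short, lengthen)
    return np.maximum(out, 0.0)


def inverse_force_velocity(fv, p: MTUParams):
    """Invert the force–velocity relation: target f_v -> v_ce [m/s].

    Targets beyond the eccentric asymptote are clamped (the returned
    velocity saturates at +v_max lengthening).
    """
    vm, n, k = p.v_max, p.fv_n, p.fv_k
    f = np.asarray(fv, dtype=float)
    f = np.clip(f, 0.0, None)
    # concentric: f = (vm+v)/(vm−kv)  =>  v = vm(f−1)/(1+kf)
    v_short = vm * (f - 1.0) / (1.0 + k * f)
    # eccentric: b = (f−n)/(n−1) = (v−vm)/(7.56 k v + vm)
    f_asym = n + (n - 1.0) / (7.56 * k)
    f_ecc = np.clip(f, None, f_asym - 1e-6)
    b = (f_ecc - n) / (n - 1.0)
    v_len = vm * (1.0 + b) / (1.0 - 7.56 * k * b)
    v = np.where(f <= 1.0, v_short, v_len)
    v = np.clip(v, -vm, vm)  # hard cap at ±v_max
    return v * p.l_opt


def _pe_force(l_ce, p: MTUParams):
    x = np.asarray(l_ce, dtype=float)
    over = np.maximum(x - p.l_opt, 0.0) / (p.l_opt * p.w)
    return p.f_max * over ** 2


def _be_force(l_ce, p: MTUParams):
    x = np.asarray(l_ce, dtype=float)
    l_min = p.l_opt * (1.0 - p.w)
    under = np.maximum(l_min - x, 0.0) / (p.l_opt * p.w / 2.0)
    return p.f_max * under ** 2


def _se_force(l_se, p: MTUParams):
    eps = np.maximum(np.asarray(l_se, dtype=float) - p.l_slack, 0.0) / p.l_slack
    return p.f_max * (eps / p.eps_ref) ** 2


def mtu_force(l_ce: float, v_ce: float, a: float, p: MTUParams):
    """Instantaneous forces of one MTU.

    Returns ``(f_ce, f_se, f_pe, f_be, f_m)`` with
    ``f_m = f_se = f_ce + f_pe − f_be`` (the CE/PE/BE side; the tendon
    transmits the net force).
    """
    if not (np.isfinite(l_ce) and np.isfinite(v_ce) and np.isfinite(a)):
        raise ValueError("non-finite muscle state")
    if l_ce <= 0:
        raise ValueError("l_ce must be positive")
    f_ce = float(p.f_max * force_length(l_ce, p) * force_velocity(v_ce, p) * a)
    f_pe = float(_pe_force(l_ce, p))
    f_be = float(_be_force(l_ce, p))
    f_m = max(f_ce + f_pe - f_be, 0.0)
    return f_ce, f_m, f_pe, f_be, f_m


def moment_arm(phi: float, att: JointAttachment):
    """Moment arm at interior angle ``phi``: constant for hip attachments,
    ``r0·cos(phi − phi_max)`` for knee/ankle."""
    if att.phi_max is None:
        return att.r0
    return att.r0 * np.cos(np.asarray(phi, dtype=float) - att.phi_max)


def mtu_length(angles: dict[str, float], p: MTUParams) -> float:
    """Total MTU length from interior joint angles.

    Normalized so that ``l_mtu = l_opt + l_slack`` when every attached
    joint sits at its reference angle; the length gradient w.r.t. each
    angle has magnitude ``rho`` times the moment arm (equal to the arm
    for an unpennated attachment, rho = 1).
    """
    l = p.l_opt + p.l_slack
    for att in p.attachments:
        phi = angles[att.joint]
        if att.phi_max is None:
            dl = -att.sign * att.rho * att.r0 * (phi - att.phi_ref)
        else:
            dl = -att.sign * att.rho * att.r0 * (
                math.sin(phi - att.phi_max) - math.sin(att.phi_ref - att.phi_max)
            )
        l += dl
    return l


def vce_from_equilibrium(l_ce: float, l_mtu: float, a: float, p: MTUParams) -> float:
    """CE velocity from the CE/SE force equilibrium.

    The tendon force at the current geometry must equal the CE+PE−BE
    force; solving ``F_SE = F_max·f_l·f_v·A + F_PE − F_BE`` for ``f_v``
    and inverting the force–velocity relation yields ``v_CE``.
    """
    l_se = l_mtu - l_ce
    if l_se < 0:
        l_se = 0.0
    f_se = float(_se_force(l_se, p))
    f_pe = float(_pe_force(l_ce, p))
    f_be = float(_be_force(l_ce, p))
    denom = p.f_max * float(force_length(l_ce, p)) * max(a, 1e-4)
    fv_target = (f_se - f_pe + f_be) / denom
    return float(inverse_force_velocity(fv_target, p))


# ---------------------------------------------------------------------------
# vectorized bank of muscles (one entry per MTU of the whole model)
# ---------------------------------------------------------------------------

class MuscleBank:
    """Fixed-size collection of MTUs integrated together.

    The contractile-element length is advanced with explicit Euler
    sub-steps (``n_sub`` per control step, default 20); activation uses
    the exact exponential update of the linear coupling ODE.
    """

    def __init__(self, params: list[MTUParams] | tuple[MTUParams, ...],
                 n_sub: int = 20):
        self.params = tuple(params)
        self.n = len(self.params)
        self.n_sub = n_sub
        self.f_max = np.array([p.f_max for p in self.params])
        self.l_opt = np.array([p.l_opt for p in self.params])
        self.l_slack = np.array([p.l_slack for p in self.params])
        self.v_max = np.array([p.v_max for p in self.params])  # [l_opt/s]
        self.w = np.array([p.w for p in self.params])
        self.c = np.array([p.c for p in self.params])
        self.fv_n = np.array([p.fv_n for p in self.params])
        self.fv_k = np.array([p.fv_k for p in self.params])
        self.eps_ref = np.array([p.eps_ref for p in self.params])
        self.reset()

    def reset(self, l_mtu: np.ndarray | None = None) -> None:
        """Reset to rest: CE at optimum unless an initial MTU length is
        given, in which case slack is allotted to the tendon first."""
        self.l_ce = self.l_opt.copy()
        if l_mtu is not None:
            self.l_ce = np.clip(l_mtu - self.l_slack,
                                0.35 * self.l_opt, 1.6 * self.l_opt)
        self.v_ce = np.zeros(self.n)
        self.act = np.zeros(self.n)
        self.stim = np.full(self.n, STIM_MIN)
        self.f_se = np.zeros(self.n)
        self.f_ce = np.zeros(self.n)
        self.f_pe = np.zeros(self.n)
        self.f_be = np.zeros(self.n)
        self._warned = False

    # -- vectorized shape functions ------------------------------------
    def _fl(self, l_ce):
        x = np.abs((l_ce - self.l_opt) / (self.l_opt * self.w))
        return np.exp(self.c * x ** 3)

    def _fv_inv(self, f):
        vm, n, k = self.v_max, self.fv_n, self.fv_k
        f = np.clip(f, 0.0, None)
        v_short = vm * (f - 1.0) / (1.0 + k * f)
        f_asym = n + (n - 1.0) / (7.56 * k)
        f_ecc = np.minimum(f, f_asym - 1e-6)
        b = (f_ecc - n) / (n - 1.0)
        v_len = vm * (1.0 + b) / (1.0 - 7.56 * k * b)
        v = np.where(f <= 1.0, v_short, v_len)
        return np.clip(v, -vm, vm)

    def _fv(self, v_norm):
        vm, n, k = self.v_max, self.fv_n, self.fv_k
        short = (vm + v_norm) / (vm - k * v_norm)
        lengthen = n + (n - 1.0) * (v_norm - vm) / (7.56 * k * v_norm + vm)
        return np.maximum(np.where(v_norm < 0.0, short, lengthen), 0.0)

    def _pe(self, l_ce):
        over = np.maximum(l_ce - self.l_opt, 0.0) / (self.l_opt * self.w)
        return self.f_max * over ** 2

    def _be(self, l_ce):
        l_min = self.l_opt * (1.0 - self.w)
        under = np.maximum(l_min - l_ce, 0.0) / (self.l_opt * self.w / 2.0)
        return self.f_max * under ** 2

    def _se(self, l_se):
        eps = np.maximum(l_se - self.l_slack, 0.0) / self.l_slack
        return self.f_max * (eps / self.eps_ref) ** 2

    # -- dynamics -------------------------------------------------------
    def step(self, l_mtu: np.ndarray, stim: np.ndarray, dt: float) -> None:
        """Advance all MTUs one control step of ``dt`` seconds.

        ``l_mtu`` is held constant across the ``n_sub`` Euler sub-steps
        of the CE length; activation is updated once with the exact
        exponential solution.
        """
        self.stim = np.clip(stim, STIM_MIN, 1.0)
        self.act = self.stim + (self.act - self.stim) * math.exp(-TAU_ACT * dt)
        np.clip(self.act, 0.0, 1.0, out=self.act)
        h = dt / self.n_sub
        act_floor = np.maximum(self.act, 1e-4)
        l_ce = self.l_ce
        for _ in range(self.n_sub):
            l_se = np.maximum(l_mtu - l_ce, 0.0)
            f_se = self._se(l_se)
            f_pe = self._pe(l_ce)
            f_be = self._be(l_ce)
            denom = self.f_max * self._fl(l_ce) * act_floor
            fv_target = (f_se - f_pe + f_be) / denom
            v_norm = self._fv_inv(fv_target)  # [l_opt/s]
            l_ce = l_ce + v_norm * self.l_opt * h
        np.clip(l_ce, 0.3 * self.l_opt, 1.7 * self.l_opt, out=l_ce)
        self.v_ce = (l_ce - self.l_ce) / dt
        self.l_ce = l_ce
        l_se = np.maximum(l_mtu - self.l_ce, 0.0)
        self.f_se = self._se(l_se)
        self.f_pe = self._pe(self.l_ce)
        self.f_be = self._be(self.l_ce)
        self.f_ce = np.maximum(self.f_se - self.f_pe + self.f_be, 0.0)
        if not np.all(np.isfinite(self.f_se)):
            if not self._warned:
                warnings.warn("non-finite muscle force; state clamped")
                self._warned = True
            np.nan_to_num(self.f_se, copy=False)

    @property
    def force(self) -> np.ndarray:
        """Net tendon force per MTU [N]."""
        return self.f_se

    @property
    def norm_force(self) -> np.ndarray:
        return self.f_se / self.f_max

    @property
    def norm_length(self) -> np.ndarray:
        return self.l_ce / self.l_opt
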