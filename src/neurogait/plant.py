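"""Planar musculoskeletal plant: a 7-segment sagittal biped.

Segments: one lumped trunk (head + arms + torso) and, per leg, thigh,
shank and foot.  Generalized coordinates (9 DoF)::

    q = [x, y, a_T, qh_L, qk_L, qa_L, qh_R, qk_R, qa_R]

``(x, y)`` is the hip point (both legs share it — the hip is rigidly
fixed to the trunk), ``a_T`` the trunk axis angle (CCW from +x; upright
is pi/2) and the six joint coordinates are *relative* rotations, zero in
the straight standing pose.  Interior joint angles, the convention used
by muscle geometry, ligaments and configuration tables, are::

    phi_hip   = pi   − q_hip      (flexion decreases the angle)
    phi_knee  = pi   + q_knee     (straight leg = 180 deg)
    phi_ankle = pi/2 + q_ankle    (standing = 90 deg, dorsiflexion larger)

Dynamics are Lagrangian: the mass matrix is assembled from COM Jacobians
(`M = sum m J'J + I w w'`), the velocity-product bias uses the exact
time derivative of the Jacobians, and contact/gravity/joint torques
enter as generalized forces.  Integration is RK4 at the control step.

Ground contact is a nonlinear spring–damper of the same functional
family as the ligament soft limit (vertical force
``k·delta·(1 + v_pen/v_ref)`` clamped at zero — the ground never pulls)
plus a horizontal stiction spring with a sliding-friction cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .muscle import MTUParams, moment_arm

__all__ = [
    "SegmentParams",
    "JointSpec",
    "ContactModel",
    "PlantState",
    "Biped",
    "DEFAULT_SEGMENTS",
    "DEFAULT_JOINTS",
    "soft_limit_torque",
    "ligament_torque",
    "contact_force",
    "grf_normalized",
    "aggregate_joint_torques",
    "interior_angles",
    "interior_velocities",
    "GRAVITY",
]

GRAVITY = 9.81

#: ligament spring stiffness [N·m/rad]
LIGAMENT_K = 17.19
#: ligament reference angular speed [rad/s]
LIGAMENT_OMEGA_REF = 1.74e-2


@dataclass(frozen=True)
class SegmentParams:
    """One rigid segment. ``com_offset`` is measured from the proximal
    joint along the segment axis."""

    name: str
    mass: float  # [kg]
    length: float  # [m]
    com_offset: float  # [m]
    inertia: float  # about COM [kg·m²]

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.length <= 0 or self.inertia <= 0:
            raise ValueError(f"{self.name}: mass, length, inertia must be positive")


@dataclass(frozen=True)
class JointSpec:
    """Soft-limit specification of one joint in interior-angle coordinates."""

    name: str
    phi_min: float  # [rad]
    phi_max: float  # [rad]
    k: float = LIGAMENT_K  # [N·m/rad]
    omega_ref: float = LIGAMENT_OMEGA_REF  # [rad/s]

    def __post_init__(self) -> None:
        if self.k <= 0 or self.omega_ref <= 0:
            raise ValueError(f"{self.name}: k and omega_ref must be positive")
        if not self.phi_min < self.phi_max:
            raise ValueError(f"{self.name}: empty limit range")


@dataclass(frozen=True)
class ContactModel:
    k_z: float = 8.0e4  # vertical stiffness [N/m]
    v_ref: float = 0.5  # damping reference speed [m/s]
    k_x: float = 8.0e3  # stiction spring stiffness [N/m]
    d_x: float = 300.0  # horizontal damping [N·s/m]
    mu: float = 0.9  # sliding friction coefficient


# Winter-style anthropometrics for an ~80 kg, 1.80 m model; the trunk
# lumps head, arms and torso into one rigid body.
DEFAULT_SEGMENTS: dict[str, SegmentParams] = {
    "trunk": SegmentParams("trunk", 53.5, 0.80, 0.35, 3.0),
    "thigh": SegmentParams("thigh", 8.5, 0.50, 0.30, 0.15),
    "shank": SegmentParams("shank", 3.5, 0.50, 0.30, 0.05),
    "foot": SegmentParams("foot", 1.25, 0.20, 0.05, 0.005),
}

DEFAULT_JOINTS: dict[str, JointSpec] = {
    "hip": JointSpec("hip", math.radians(110.0), math.radians(220.0)),
    "knee": JointSpec("knee", math.radians(45.0), math.radians(180.0)),
    "ankle": JointSpec("ankle", math.radians(60.0), math.radians(130.0)),
}

#: heel and toe lie on the foot axis at these offsets from the ankle [m]
FOOT_HEEL_OFFSET = -0.05
FOOT_TOE_OFFSET = 0.15


@dataclass
class PlantState:
    q: np.ndarray  # (9,)
    qd: np.ndarray  # (9,)
    # stiction anchors, x of [heel_L, toe_L, heel_R, toe_R]
    anchors: np.ndarray = field(default_factory=lambda: np.zeros(4))
    # last evaluated planar contact forces, (4, 2)
    contact_forces: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))

    def copy(self) -> "PlantState":
        return PlantState(self.q.copy(), self.qd.copy(),
                          self.anchors.copy(), self.contact_forces.copy())


# ---------------------------------------------------------------------------
# ligament soft limit
# ---------------------------------------------------------------------------

def soft_limit_torque(dphi: float, omega: float, k: float = LIGAMENT_K,
                      omega_ref: float = LIGAMENT_OMEGA_REF) -> float:
    """Nonlinear spring–damper soft-limit law.

    ``dphi`` is the over-travel beyond the limit (positive once the limit
    is passed) and ``omega`` the angular speed oriented positive toward /
    past the limit.  The torque opposes the over-travel; it is exactly
    zero while inside the range (``dphi <= 0``) or when the joint
    retracts faster than the reference speed (``omega/omega_ref <= -1``).
    """
    if not (np.isfinite(dphi) and np.isfinite(omega)):
        raise ValueError("non-finite ligament input")
    if dphi > 0.0 and omega / omega_ref > -1.0:
        return k * dphi * (1.0 + omega / omega_ref)
    return 0.0


def ligament_torque(phi: float, omega: float, joint: JointSpec) -> float:
    """Signed restoring torque of both soft limits of one joint.

    ``phi``/``omega`` are the interior angle and its rate.  A positive
    return value pushes the angle up (lower-limit response); a negative
    one pushes it down (upper-limit response).
    """
    tau = 0.0
    # upper limit: over-travel grows with phi, "toward" means omega > 0
    tau -= soft_limit_torque(phi - joint.phi_max, omega, joint.k, joint.omega_ref)
    # lower limit: over-travel grows as phi decreases
    tau += soft_limit_torque(joint.phi_min - phi, -omega, joint.k, joint.omega_ref)
    return tau


# ---------------------------------------------------------------------------
# ground contact
# ---------------------------------------------------------------------------

def _elevation(ground: np.ndarray, x: float) -> float:
    return float(np.interp(x, ground[:, 0], ground[:, 1]))


def contact_force(pos: np.ndarray, vel: np.ndarray, anchor_x: float,
                  ground: np.ndarray, model: ContactModel
                  ) -> tuple[np.ndarray, float]:
    """Planar contact force on one point and the updated stiction anchor.

    Zero without penetration; the vertical component is never negative
    (the ground pushes, never pulls) and is continuous in the
    penetration depth at zero.  The horizontal component is a stiction
    spring saturated by the sliding-friction cone ``|f_x| <= mu f_y``.
    """
    x, y = float(pos[0]), float(pos[1])
    depth = _elevation(ground, x) - y
    if depth <= 0.0:
        return np.zeros(2), x
    v_pen = -float(vel[1])  # downward velocity deepens penetration
    f_y = model.k_z * depth * (1.0 + v_pen / model.v_ref)
    f_y = max(f_y, 0.0)
    f_x = -model.k_x * (x - anchor_x) - model.d_x * float(vel[0])
    limit = model.mu * f_y
    new_anchor = anchor_x
    if f_x > limit:
        f_x = limit
        new_anchor = x + (f_x + model.d_x * float(vel[0])) / model.k_x
    elif f_x < -limit:
        f_x = -limit
        new_anchor = x + (f_x + model.d_x * float(vel[0])) / model.k_x
    return np.array([f_x, f_y]), new_anchor


def grf_normalized(toe_force: float, heel_force: float, total_weight: float) -> float:
    """Per-foot ground sensor: (toe + heel) vertical force over body weight."""
    if total_weight <= 0:
        raise ValueError("total_weight must be positive")
    return max(toe_force + heel_force, 0.0) / total_weight


# ---------------------------------------------------------------------------
# muscle/ligament torque aggregation (interior-angle coordinates)
# ---------------------------------------------------------------------------

def aggregate_joint_torques(mtu_forces: dict[str, float],
                            angles: dict[str, float],
                            muscles: list[MTUParams] | tuple[MTUParams, ...],
                            ligament_torques: dict[str, float] | None = None,
                            ) -> dict[str, float]:
    """Per-joint torque ``tau_j = sum_m tau_{m,j} + tau_j^lig`` for one limb.

    Bi-articular muscles (HAM, GAS) contribute to both of their joints.
    The result is linear in the muscle forces.
    """
    tau = {j: 0.0 for j in ("hip", "knee", "ankle")}
    by_name = {p.name: p for p in muscles}
    for name, f in mtu_forces.items():
        if name not in by_name:
            raise KeyError(f"unknown muscle {name!r}")
        for att in by_name[name].attachments:
            if att.joint not in tau:
                raise KeyError(f"unknown joint {att.joint!r}")
            r = float(moment_arm(angles[att.joint], att))
            tau[att.joint] += att.sign * f * r
    if ligament_torques:
        for j, t in ligament_torques.items():
            tau[j] += t
    return tau


def interior_angles(q: np.ndarray) -> dict[str, np.ndarray]:
    """Interior joint angles (L, R) from generalized coordinates."""
    return {
        "hip": np.array([math.pi - q[3], math.pi - q[6]]),
        "knee": np.array([math.pi + q[4], math.pi + q[7]]),
        "ankle": np.array([math.pi / 2 + q[5], math.pi / 2 + q[8]]),
    }


def interior_velocities(qd: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "hip": np.array([-qd[3], -qd[6]]),
        "knee": np.array([qd[4], qd[7]]),
        "ankle": np.array([qd[5], qd[8]]),
    }


# map interior-angle torques onto generalized coordinates: dphi/dq
_DPHI_DQ = {"hip": -1.0, "knee": 1.0, "ankle": 1.0}


# ---------------------------------------------------------------------------
# the articulated biped
# ---------------------------------------------------------------------------

# segment order: trunk, thighL, shankL, footL, thighR, shankR, footR
_SUBTREE = {2: (0, 1, 2, 3, 4, 5, 6),
            3: (1, 2, 3), 4: (2, 3), 5: (3,),
            6: (4, 5, 6), 7: (5, 6), 8: (6,)}


class Biped:
    """Articulated planar biped with contact, gravity and joint torques."""

    def __init__(self,
                 segments: dict[str, SegmentParams] | None = None,
                 joints: dict[str, JointSpec] | None = None,
                 contact: ContactModel | None = None,
                 ground: np.ndarray | None = None,
                 gravity: float = GRAVITY):
        self.segments = dict(segments or DEFAULT_SEGMENTS)
        self.joints = dict(joints or DEFAULT_JOINTS)
        self.contact = contact or ContactModel()
        self.ground = (np.asarray(ground, dtype=float) if ground is not None
                       else np.array([[-1e4, 0.0], [1e4, 0.0]]))
        self.g = gravity
        sg = self.segments
        self.masses = np.array([sg["trunk"].mass] + [sg[n].mass for n in
                               ("thigh", "shank", "foot")] * 2)
        self.inertias = np.array([sg["trunk"].inertia] + [sg[n].inertia for n in
                                 ("thigh", "shank", "foot")] * 2)
        self.total_mass = float(self.masses.sum())
        self.weight = self.total_mass * self.g
        # GRF sensor normalizer; falls back to standard gravity so the
        # sensor stays defined in zero-g test configurations
        self.ref_weight = self.total_mass * (self.g if self.g > 0 else GRAVITY)
        # constant angular-velocity rows w_s (7 x 9)
        W = np.zeros((7, 9))
        for s in range(7):
            W[s, 2] = 1.0
        for j, segs in _SUBTREE.items():
            if j == 2:
                continue
            for s in segs:
                W[s, j] = 1.0
        self._W = W
        self._IW = self.inertias[:, None, None] * W[:, :, None] * W[:, None, :]

    # -- kinematics -----------------------------------------------------
    def kinematics(self, q: np.ndarray, qd: np.ndarray):
        """Positions, Jacobians and their rates for all segments.

        Returns a dict with COM positions/velocities (7,2), COM Jacobians
        J (7,2,9), Jdot@qd (7,2), joint points and contact-point data.
        """
        sg = self.segments
        x, y, aT = q[0], q[1], q[2]
        a_thL = aT + math.pi + q[3]
        a_shL = a_thL + q[4]
        a_ftL = a_shL + math.pi / 2 + q[5]
        a_thR = aT + math.pi + q[6]
        a_shR = a_thR + q[7]
        a_ftR = a_shR + math.pi / 2 + q[8]

        def u(a):
            return np.array([math.cos(a), math.sin(a)])

        H = np.array([x, y])
        uT, uthL, ushL, uftL = u(aT), u(a_thL), u(a_shL), u(a_ftL)
        uthR, ushR, uftR = u(a_thR), u(a_shR), u(a_ftR)
        KL = H + sg["thigh"].length * uthL
        AL = KL + sg["shank"].length * ushL
        KR = H + sg["thigh"].length * uthR
        AR = KR + sg["shank"].length * ushR
        coms = np.empty((7, 2))
        coms[0] = H + sg["trunk"].com_offset * uT
        coms[1] = H + sg["thigh"].com_offset * uthL
        coms[2] = KL + sg["shank"].com_offset * ushL
        coms[3] = AL + sg["foot"].com_offset * uftL
        coms[4] = H + sg["thigh"].com_offset * uthR
        coms[5] = KR + sg["shank"].com_offset * ushR
        coms[6] = AR + sg["foot"].com_offset * uftR

        pivots = {2: H, 3: H, 4: KL, 5: AL, 6: H, 7: KR, 8: AR}
        J = np.zeros((7, 2, 9))
        J[:, 0, 0] = 1.0
        J[:, 1, 1] = 1.0
        for j, segs in _SUBTREE.items():
            o = pivots[j]
            for s in segs:
                r = coms[s] - o
                J[s, 0, j] = -r[1]
                J[s, 1, j] = r[0]
        com_vel = np.einsum("sij,j->si", J, qd)

        vH = qd[:2]
        a_thL_d = qd[2] + qd[3]
        a_shL_d = a_thL_d + qd[4]
        a_ftL_d = a_shL_d + qd[5]
        a_thR_d = qd[2] + qd[6]
        a_shR_d = a_thR_d + qd[7]
        a_ftR_d = a_shR_d + qd[8]

        def perp(v):
            return np.array([-v[1], v[0]])

        vKL = vH + a_thL_d * perp(KL - H)
        vAL = vKL + a_shL_d * perp(AL - KL)
        vKR = vH + a_thR_d * perp(KR - H)
        vAR = vKR + a_shR_d * perp(AR - KR)
        pivot_vel = {2: vH, 3: vH, 4: vKL, 5: vAL, 6: vH, 7: vKR, 8: vAR}

        # Jdot @ qd, exactly: column j of Jdot is perp(pdot_s - v_pivot_j)
        Jdot_qd = np.zeros((7, 2))
        for j, segs in _SUBTREE.items():
            vo = pivot_vel[j]
            for s in segs:
                rdot = com_vel[s] - vo
                Jdot_qd[s] += qd[j] * np.array([-rdot[1], rdot[0]])

        # contact points on the feet: heel_L, toe_L, heel_R, toe_R
        pts = np.empty((4, 2))
        pts[0] = AL + FOOT_HEEL_OFFSET * uftL
        pts[1] = AL + FOOT_TOE_OFFSET * uftL
        pts[2] = AR + FOOT_HEEL_OFFSET * uftR
        pts[3] = AR + FOOT_TOE_OFFSET * uftR
        pt_vel = np.empty((4, 2))
        pt_vel[0] = vAL + a_ftL_d * perp(pts[0] - AL)
        pt_vel[1] = vAL + a_ftL_d * perp(pts[1] - AL)
        pt_vel[2] = vAR + a_ftR_d * perp(pts[2] - AR)
        pt_vel[3] = vAR + a_ftR_d * perp(pts[3] - AR)
        pt_chain = ((2, 3, 4, 5), (2, 3, 4, 5), (2, 6, 7, 8), (2, 6, 7, 8))
        Jpts = np.zeros((4, 2, 9))
        Jpts[:, 0, 0] = 1.0
        Jpts[:, 1, 1] = 1.0
        for i in range(4):
            for j in pt_chain[i]:
                r = pts[i] - pivots[j]
                Jpts[i, 0, j] = -r[1]
                Jpts[i, 1, j] = r[0]
        return {
            "coms": coms, "com_vel": com_vel, "J": J, "Jdot_qd": Jdot_qd,
            "points": {"hip": H, "knee_L": KL, "ankle_L": AL,
                       "knee_R": KR, "ankle_R": AR},
            "contact_pts": pts, "contact_vel": pt_vel, "Jpts": Jpts,
        }

    # -- forces ---------------------------------------------------------
    def _contact_eval(self, kin, anchors):
        forces = np.zeros((4, 2))
        new_anchors = anchors.copy()
        for i in range(4):
            f, a = contact_force(kin["contact_pts"][i], kin["contact_vel"][i],
                                 anchors[i], self.ground, self.contact)
            forces[i] = f
            new_anchors[i] = a
        return forces, new_anchors

    def joint_generalized_torques(self, tau_interior: dict[str, np.ndarray]
                                  ) -> np.ndarray:
        """Map per-joint interior-angle torques (L, R) to generalized forces."""
        Q = np.zeros(9)
        idx = {"hip": (3, 6), "knee": (4, 7), "ankle": (5, 8)}
        for joint, (jL, jR) in idx.items():
            s = _DPHI_DQ[joint]
            Q[jL] += s * tau_interior[joint][0]
            Q[jR] += s * tau_interior[joint][1]
        return Q

    def ligament_interior_torques(self, q: np.ndarray, qd: np.ndarray
                                  ) -> dict[str, np.ndarray]:
        ang = interior_angles(q)
        vel = interior_velocities(qd)
        out = {}
        for joint in ("hip", "knee", "ankle"):
            spec = self.joints[joint]
            out[joint] = np.array([
                ligament_torque(float(ang[joint][i]), float(vel[joint][i]), spec)
                for i in range(2)])
        return out

    def accel(self, q, qd, Q_joint, ext_forces=None, anchors=None,
              with_contact=True):
        """Generalized accelerations; ``Q_joint`` already in generalized
        coordinates.  ``ext_forces`` is a list of (segment_index, force)
        planar forces applied at segment COMs (e.g. trunk pushes)."""
        kin = self.kinematics(q, qd)
        J = kin["J"]
        M = np.einsum("s,sij,sik->jk", self.masses, J, J) + self._IW.sum(axis=0)
        h = np.einsum("s,sij,si->j", self.masses, J, kin["Jdot_qd"])
        Q = Q_joint - h
        Q += -self.g * (self.masses[:, None] * J[:, 1, :]).sum(axis=0)
        if with_contact and anchors is not None:
            forces, _ = self._contact_eval(kin, anchors)
            Q += np.einsum("pij,pi->j", kin["Jpts"], forces)
        if ext_forces:
            for s, f in ext_forces:
                Q += J[s].T @ np.asarray(f, dtype=float)
        return np.linalg.solve(M, Q)

    def step_dynamics(self, state: PlantState, Q_joint: np.ndarray,
                      ext_forces=None, dt: float = 1e-3,
                      with_contact: bool = True) -> PlantState:
        """One RK4 step of the rigid-body dynamics.

        Joint torques and external pushes are held over the step; contact
        forces are re-evaluated at every RK4 stage with frozen stiction
        anchors, which are updated once from the post-step state.
        """
        if not np.all(np.isfinite(Q_joint)):
            raise ValueError("non-finite joint torques")
        q0, qd0 = state.q, state.qd
        anch = state.anchors

        def f(q, qd):
            return qd, self.accel(q, qd, Q_joint, ext_forces, anch, with_contact)

        k1q, k1v = f(q0, qd0)
        k2q, k2v = f(q0 + 0.5 * dt * k1q, qd0 + 0.5 * dt * k1v)
        k3q, k3v = f(q0 + 0.5 * dt * k2q, qd0 + 0.5 * dt * k2v)
        k4q, k4v = f(q0 + dt * k3q, qd0 + dt * k3v)
        q = q0 + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qd = qd0 + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        new = PlantState(q, qd, anch.copy())
        if with_contact:
            kin = self.kinematics(q, qd)
            forces, new_anchors = self._contact_eval(kin, anch)
            new.anchors = new_anchors
            new.contact_forces = forces
        return new

    # -- observables ----------------------------------------------------
    def foot_grf(self, state: PlantState) -> np.ndarray:
        """Normalized per-foot ground sensor values (L, R)."""
        f = state.contact_forces
        return np.array([
            grf_normalized(f[1, 1], f[0, 1], self.ref_weight),
            grf_normalized(f[3, 1], f[2, 1], self.ref_weight),
        ])

    def trunk_pitch(self, state: PlantState) -> tuple[float, float]:
        """Forward-positive trunk pitch and pitch rate."""
        return math.pi / 2 - float(state.q[2]), -float(state.qd[2])

    def com(self, state: PlantState) -> np.ndarray:
        kin = self.kinematics(state.q, state.qd)
        return (self.masses[:, None] * kin["coms"]).sum(axis=0) / self.total_mass

    def total_energy(self, state: PlantState) -> float:
        """Kinetic + gravitational potential energy (no contact stored
        energy); used by conservation tests on passive configurations."""
        kin = self.kinematics(state.q, state.qd)
        J = kin["J"]
        M = np.einsum("s,sij,sik->jk", self.masses, J, J) + self._IW.sum(axis=0)
        ke = 0.5 * state.qd @ M @ state.qd
        pe = self.g * float((self.masses * kin["coms"][:, 1]).sum())
        return float(ke + pe)

    def standing_state(self, x: float = 0.0, forward_speed: float = 0.0,
                       leg_split: float = 0.0, pitch: float = 0.0) -> PlantState:
        """Upright pose with feet at ground level.

        ``leg_split`` swings the left leg forward and the right leg back
        by that hip angle [rad]; ``pitch`` is forward-positive lean.
        """
        sg = self.segments
        leg = sg["thigh"].length + sg["shank"].length
        q = np.zeros(9)
        q[0] = x
        q[2] = math.pi / 2 - pitch
        q[3] = leg_split
        q[6] = -leg_split
        # place the feet at the static equilibrium penetration of the
        # four contact springs so standing starts force-balanced
        sink = self.weight / (4.0 * self.contact.k_z)
        q[1] = _elevation(self.ground, x) + leg * math.cos(leg_split) - sink
        qd = np.zeros(9)
        qd[0] = forward_speed
        st = PlantState(q, qd)
        kin = self.kinematics(q, qd)
        st.anchors = kin["contact_pts"][:, 0].copy()
        return st

    def standing_com_height(self) -> float:
        sg = self.segments
        return (sg["thigh"].length + sg["shank"].length) + 0.0  # hip height

    def has_fallen(self, state: PlantState) -> bool:
        """Trunk COM below 70% of its standing height or pitch beyond 60 deg."""
        if not np.all(np.isfinite(state.q)) or not np.all(np.isfinite(state.qd)):
            return True
        pitch, _ = self.trunk_pitch(state)
        sg = self.segments
        standing = self.standing_com_height() + sg["trunk"].com_offset
        trunk_com_y = state.q[1] + sg["trunk"].com_offset * math.sin(state.q[2])
        ground_y = _elevation(self.ground, float(state.q[0]))
        return (trunk_com_y - ground_y) < 0.7 * standing or abs(pitch) > math.radians(60)
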