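"""Planar seven-link skeleton: forward kinematics, contact, equations of
motion and the closed-loop forward simulation.

The skeleton has nine generalized coordinates: trunk-COM translation (x, y),
trunk pitch theta (CCW-positive; positive is a backward lean when travelling
along +x), and flexion-positive hip/knee/ankle angles per leg.  The equations
of motion ``M(q) qdd = h(q, qd) + Q`` are assembled segment-by-segment from
chain Jacobians (see :mod:`synergait._engine` for the packed kernels) and
integrated with fixed-step classical Runge-Kutta.

Foot-ground interaction uses four viscoelastic points per sole: a unilateral
normal spring-damper and a tangential spring-damper anchored at the touchdown
position (anchor slips when the elastic force exceeds the friction cone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import yaml

from . import _engine
from .motor_control import MUSCLES, PulseParameters, RegulatorParameters
from .muscle_model import MuscleSet
from .record import GaitRecord

__all__ = [
    "BodyParameters",
    "SkeletonState",
    "kinematics",
    "segment_coms",
    "whole_body_com",
    "contact_forces",
    "joint_passive_torques",
    "equations_of_motion",
    "mass_matrix",
    "total_energy",
    "rk4_step",
    "initial_state",
    "pack_control",
    "simulate",
]

GRAVITY = 9.81


@dataclass
class BodyParameters:
    """Segment, joint and contact constants of the seven-link body.

    Defaults are an anthropometric table (Winter segment fractions) scaled to
    a 63.3 kg, 1.66 m subject.  Lengths in m, masses in kg, inertias about the
    segment COM in kg m^2, joint viscosities in N m s/rad.  ``d_hip`` is the
    distance from the hip to the trunk (head-arms-torso) COM along the trunk
    axis; the foot frame hangs the sole ``h_sole`` below the ankle with four
    contact points at along-axis offsets ``sole_offsets`` from the ankle
    (heel negative, toe positive).
    """

    m_trunk: float = 42.92
    i_trunk: float = 2.70
    d_hip: float = 0.30
    m_thigh: float = 6.33
    i_thigh: float = 0.109
    l_thigh: float = 0.407
    c_thigh: float = 0.176
    m_shank: float = 2.94
    i_shank: float = 0.045
    l_shank: float = 0.408
    c_shank: float = 0.177
    m_foot: float = 0.92
    i_foot: float = 0.013
    c_foot_ax: float = 0.06
    c_foot_pp: float = 0.04
    h_sole: float = 0.065
    sole_offsets: tuple = (-0.063, 0.02, 0.10, 0.185)
    k_contact: float = 8.0e4
    c_contact: float = 1.0e3
    k_tangent: float = 2.0e4
    c_tangent: float = 6.0e2
    mu: float = 1.2
    g: float = GRAVITY
    c_hip: float = 1.5
    c_knee: float = 1.5
    c_ankle: float = 1.0
    knee_limits: tuple = (0.1, 2.8)
    ankle_limits: tuple = (-1.0, 0.54)
    k_limit: float = 1000.0
    c_limit: float = 50.0

    def packed(self) -> np.ndarray:
        bp = np.zeros(35)
        bp[0] = self.m_trunk
        bp[1] = self.i_trunk
        bp[2] = self.d_hip
        bp[3] = self.m_thigh
        bp[4] = self.i_thigh
        bp[5] = self.l_thigh
        bp[6] = self.c_thigh
        bp[7] = self.m_shank
        bp[8] = self.i_shank
        bp[9] = self.l_shank
        bp[10] = self.c_shank
        bp[11] = self.m_foot
        bp[12] = self.i_foot
        bp[13] = self.c_foot_ax
        bp[14] = self.c_foot_pp
        bp[15] = self.h_sole
        bp[16:20] = self.sole_offsets
        bp[20] = self.k_contact
        bp[21] = self.c_contact
        bp[22] = self.k_tangent
        bp[23] = self.c_tangent
        bp[24] = self.mu
        bp[25] = self.g
        bp[26] = self.c_hip
        bp[27] = self.c_knee
        bp[28] = self.c_ankle
        bp[29:31] = self.knee_limits
        bp[31:33] = self.ankle_limits
        bp[33] = self.k_limit
        bp[34] = self.c_limit
        return bp

    @property
    def total_mass(self) -> float:
        return self.m_trunk + 2 * (self.m_thigh + self.m_shank + self.m_foot)

    @property
    def standing_height(self) -> float:
        """Trunk-COM height in upright stance with the sole on the ground."""
        return self.h_sole + self.l_shank + self.l_thigh + self.d_hip

    @classmethod
    def from_yaml(cls, path) -> "BodyParameters":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["sole_offsets"] = tuple(doc.get("sole_offsets", cls.sole_offsets))
        doc["knee_limits"] = tuple(doc.get("knee_limits", cls.knee_limits))
        doc["ankle_limits"] = tuple(doc.get("ankle_limits", cls.ankle_limits))
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {
            k: ([float(x) for x in v] if isinstance(v, (tuple, list)) else float(v))
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class SkeletonState:
    """Generalized coordinates/velocities and time."""

    q: np.ndarray = field(default_factory=lambda: np.zeros(9))
    qd: np.ndarray = field(default_factory=lambda: np.zeros(9))
    t: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        if self.q.shape != (9,) or self.qd.shape != (9,):
            raise ValueError("q and qd must have shape (9,)")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _chain_angles(q: np.ndarray) -> dict:
    """Absolute segment-axis angles (batched over leading axes of q)."""
    th = q[..., 2]
    out = {}
    for leg, b in (("r", 3), ("l", 6)):
        psi1 = th + q[..., b]
        psi2 = psi1 - q[..., b + 1]
        chi = psi2 + 0.5 * np.pi + q[..., b + 2]
        out[leg] = (psi1, psi2, chi)
    return out


def segment_coms(q: np.ndarray, body: BodyParameters) -> tuple[np.ndarray, np.ndarray]:
    """Segment-COM world positions (..., 7, 2) and masses (7,).

    Segment order: trunk, thighR, shankR, footR, thighL, shankL, footL.
    """
    q = np.asarray(q, dtype=float)
    th = q[..., 2]
    hip = np.stack(
        [q[..., 0] + body.d_hip * np.sin(th), q[..., 1] - body.d_hip * np.cos(th)],
        axis=-1,
    )
    ang = _chain_angles(q)
    coms = [np.stack([q[..., 0], q[..., 1]], axis=-1)]
    masses = [body.m_trunk]
    for leg in ("r", "l"):
        psi1, psi2, chi = ang[leg]
        d1 = np.stack([np.sin(psi1), -np.cos(psi1)], axis=-1)
        d2 = np.stack([np.sin(psi2), -np.cos(psi2)], axis=-1)
        knee = hip + body.l_thigh * d1
        ankle = knee + body.l_shank * d2
        f = np.stack([np.sin(chi), -np.cos(chi)], axis=-1)
        n = np.stack([-np.cos(chi), -np.sin(chi)], axis=-1)
        coms.append(hip + body.c_thigh * d1)
        coms.append(knee + body.c_shank * d2)
        coms.append(ankle + body.c_foot_ax * f + body.c_foot_pp * n)
        masses.extend([body.m_thigh, body.m_shank, body.m_foot])
    return np.stack(coms, axis=-2), np.asarray(masses)


def whole_body_com(
    q: np.ndarray, body: BodyParameters, qd: np.ndarray | None = None
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Whole-body COM position (..., 2); with ``qd`` also its velocity."""
    coms, masses = segment_coms(q, body)
    w = masses / masses.sum()
    pos = np.einsum("...sk,s->...k", coms, w)
    if qd is None:
        return pos
    eps = 1e-7
    coms2, _ = segment_coms(np.asarray(q) + eps * np.asarray(qd), body)
    pos2 = np.einsum("...sk,s->...k", coms2, w)
    return pos, (pos2 - pos) / eps


def kinematics(state: SkeletonState, body: BodyParameters) -> dict:
    """Forward kinematics: joint points, sole contact points (positions and
    velocities), segment COMs and whole-body COM."""
    M, h, sp, sv, sJ = _engine.kin_eom(state.q, state.qd, body.packed())
    coms, masses = segment_coms(state.q, body)
    th = state.q[2]
    hip = np.array(
        [state.q[0] + body.d_hip * np.sin(th), state.q[1] - body.d_hip * np.cos(th)]
    )
    ang = _chain_angles(state.q)
    out = {
        "hip": hip,
        "sole_pos": np.asarray(sp),
        "sole_vel": np.asarray(sv),
        "sole_jac": np.asarray(sJ),
        "segment_coms": coms,
        "com": (coms * (masses / masses.sum())[:, None]).sum(axis=0),
    }
    for leg in ("r", "l"):
        psi1, psi2, chi = ang[leg]
        d1 = np.array([np.sin(psi1), -np.cos(psi1)])
        d2 = np.array([np.sin(psi2), -np.cos(psi2)])
        out[f"knee_{leg}"] = hip + body.l_thigh * d1
        out[f"ankle_{leg}"] = out[f"knee_{leg}"] + body.l_shank * d2
    return out


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def mass_matrix(q: np.ndarray, body: BodyParameters) -> np.ndarray:
    M, _, _, _, _ = _engine.kin_eom(np.asarray(q, float), np.zeros(9), body.packed())
    return np.asarray(M)


def contact_forces(
    state: SkeletonState,
    body: BodyParameters,
    anchors: np.ndarray | None = None,
    active: np.ndarray | None = None,
) -> dict:
    """Sole-point forces and per-foot ground reaction forces at one state.

    Without anchor bookkeeping (fresh call), anchors are taken at the current
    positions of penetrating points, so tangential elastic force is zero and
    only damping acts.
    """
    bp = body.packed()
    _, _, sp, sv, _ = _engine.kin_eom(state.q, state.qd, bp)
    if anchors is None:
        anchors = np.asarray(sp)[:, :, 0].copy()
    if active is None:
        active = (np.asarray(sp)[:, :, 1] < 0).astype(np.int64)
    f = np.asarray(
        _engine.contact_forces(np.asarray(sp), np.asarray(sv), anchors, active, bp)
    )
    return {
        "point_forces": f,
        "grf_r": f[0].sum(axis=0),
        "grf_l": f[1].sum(axis=0),
        "sole_pos": np.asarray(sp),
        "sole_vel": np.asarray(sv),
    }


def joint_passive_torques(state: SkeletonState, body: BodyParameters) -> np.ndarray:
    """Viscous plus joint-limit torques, (6,): hipR kneeR ankleR hipL kneeL ankleL."""
    return np.asarray(_engine.passive_joint_torques(state.q, state.qd, body.packed()))


def equations_of_motion(
    state: SkeletonState,
    joint_torques: np.ndarray,
    point_forces: np.ndarray,
    body: BodyParameters,
) -> np.ndarray:
    """Generalized accelerations for applied joint torques (6,) and sole-point
    forces (2, 4, 2)."""
    bp = body.packed()
    M, h, sp, sv, sJ = _engine.kin_eom(state.q, state.qd, bp)
    M = np.asarray(M)
    if np.linalg.cond(M) > 1e12:
        raise ValueError("singular mass matrix; check BodyParameters")
    Q = np.asarray(h).copy()
    jt = np.asarray(joint_torques, dtype=float)
    Q[3:9] += jt
    f = np.asarray(point_forces, dtype=float)
    sJ = np.asarray(sJ)
    for leg in range(2):
        for i in range(4):
            Q += sJ[leg, i, 0] * f[leg, i, 0] + sJ[leg, i, 1] * f[leg, i, 1]
    return np.linalg.solve(M, Q)


def total_energy(state: SkeletonState, body: BodyParameters) -> float:
    """Kinetic plus gravitational potential energy of the skeleton."""
    M = np.asarray(_engine.kin_eom(state.q, state.qd, body.packed())[0])
    ke = 0.5 * float(state.qd @ M @ state.qd)
    coms, masses = segment_coms(state.q, body)
    pe = float((masses * coms[:, 1]).sum() * body.g)
    return ke + pe


def rk4_step(y: np.ndarray, dt: float, f: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of ``dy/dt = f(y)``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    out = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state after RK4 step")
    return out


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

def pack_control(
    pp: PulseParameters, rp: RegulatorParameters, u_max: float = 1.5
) -> np.ndarray:
    """Pack movement-generator and movement-regulator parameters for the engine."""
    ctrl = np.zeros(71)
    ctrl[0] = pp.T
    ctrl[1:6] = pp.onset
    ctrl[6:11] = pp.duration
    ctrl[11:16] = pp.amplitude
    ctrl[16:61] = pp.weights.reshape(-1)
    ctrl[61] = rp.kappa_IL
    ctrl[62] = rp.kappa_GM
    ctrl[63] = rp.sigma_IL
    ctrl[64] = rp.sigma_GM
    ctrl[65] = rp.lambda_TA
    ctrl[66] = rp.lambda_SO
    ctrl[67] = rp.theta_ref
    ctrl[68] = rp.v_ref
    ctrl[69] = rp.tau
    ctrl[70] = u_max
    return ctrl


#: Default launch: late right swing, an instant before right touchdown
#: (oscillator phase just below 2*pi), with the trailing left leg still loaded
#: on its forefoot and gait-like joint velocities.  The first strides are a
#: settling transient and are excluded from steady-state metrics.
DEFAULT_POSTURE = {
    "theta": 0.01,
    "hip_r": 0.45,
    "knee_r": 0.15,
    "ankle_r": 0.15,
    "hip_l": -0.18,
    "knee_l": 0.50,
    "ankle_l": 0.00,
    "dhip_r": -0.3,
    "dknee_r": -1.0,
    "dankle_r": 0.0,
    "dhip_l": -0.5,
    "dknee_l": 1.0,
    "dankle_l": -1.0,
    "dtheta": 0.0,
}
DEFAULT_PHI0 = 0.95 * 2 * np.pi


def initial_state(
    body: BodyParameters,
    posture: dict | None = None,
    v0: float = 1.40,
    vy0: float = -0.10,
    phi0: float = DEFAULT_PHI0,
    penetration: float = 1e-3,
) -> np.ndarray:
    """Packed initial state (37,) with the lowest sole point just touching.

    The trunk height is solved so the deepest contact point sits
    ``penetration`` below the ground plane; activations start at zero and are
    seeded from the launch-phase synergy command by :func:`simulate`.
    ``posture`` may override joint angles, their rates (``d`` prefix) and the
    trunk pitch.
    """
    p = dict(DEFAULT_POSTURE)
    if posture:
        p.update(posture)
    q = np.zeros(9)
    qd = np.zeros(9)
    q[2] = p["theta"]
    qd[2] = p.get("dtheta", 0.0)
    for k, name in enumerate(("hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")):
        q[3 + k] = p[name]
        qd[3 + k] = p.get("d" + name, 0.0)
    _, _, sp, _, _ = _engine.kin_eom(q, np.zeros(9), body.packed())
    y_min = np.asarray(sp)[:, :, 1].min()
    q[1] = -y_min - penetration
    qd[0] = v0
    qd[1] = vy0
    y = np.zeros(37)
    y[0:9] = q
    y[9:18] = qd
    y[36] = phi0 % (2 * np.pi)
    return y


def simulate(
    body: BodyParameters,
    muscles: MuscleSet,
    pulses: PulseParameters,
    regulator: RegulatorParameters,
    duration: float,
    dt: float = 2e-5,
    decimate: float = 1e-3,
    y0: np.ndarray | None = None,
    u_max: float = 1.5,
    stance_threshold: float = 5.0,
    debounce: float = 0.02,
    fall_height_fraction: float = 0.6,
    fall_pitch: float = 1.0,
    min_steps: int = 10,
    meta: dict | None = None,
) -> GaitRecord:
    """Run the closed loop (motor control -> muscles -> skeleton) and record.

    The control step equals the integrator step ``dt``; outputs are decimated
    to the ``decimate`` interval.  The run terminates early when the trunk COM
    drops below ``fall_height_fraction`` of standing height or trunk pitch
    exceeds ``fall_pitch`` (recorded as a failed run, not an exception);
    ``success`` additionally requires at least ``min_steps`` touchdowns.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    bp = body.packed()
    mp, msc = muscles.packed()
    ctrl = pack_control(pulses, regulator, u_max=u_max)
    if y0 is None:
        y0 = initial_state(body)
    y0 = np.asarray(y0, dtype=float).copy()
    # seed activations at the launch-phase synergy command to avoid a jolt
    if not y0[18:36].any():
        u_syn = np.zeros(18)
        _engine.synergy_commands(float(y0[36]), ctrl, u_syn)
        y0[18:36] = np.clip(u_syn, 0.0, 1.0)

    anchors = np.zeros((2, 4))
    active = np.zeros((2, 4), dtype=np.int64)
    n_steps = int(round(duration / dt))
    decim = max(int(round(decimate / dt)), 1)
    y_fall = fall_height_fraction * body.standing_height

    (
        t, q, qd, a, phi, u, u_syn, u_reg, forces, grf, stance,
        td_time, td_leg, lo_time, lo_leg, status, t_end, y_end,
    ) = _engine.simulate_loop(
        y0, anchors, active, bp, mp, msc, ctrl, dt, n_steps, decim,
        y_fall, fall_pitch, stance_threshold, debounce,
    )

    if status == _engine.DIVERGED:
        raise FloatingPointError(
            f"non-finite dynamics at t={t_end:.4f} s; last valid state recorded"
        )

    # success follows the behavioural criterion: the model kept going without
    # falling over for at least `min_steps` touchdowns (a later fall does not
    # retract the steps already taken)
    run_meta = {
        "dt": dt,
        "decimate": decimate,
        "duration": duration,
        "T": pulses.T,
        "u_max": u_max,
        "status": "fell" if status == _engine.FELL else "ok",
        "fell": bool(status == _engine.FELL),
        "t_end": float(t_end),
        "td_time": np.asarray(td_time),
        "td_leg": np.asarray(td_leg),
        "lo_time": np.asarray(lo_time),
        "lo_leg": np.asarray(lo_leg),
        "steps": int(len(td_time)),
        "success": bool(len(td_time) >= min_steps),
        "final_state": np.asarray(y_end),
    }
    if meta:
        run_meta.update(meta)
    return GaitRecord.from_arrays(
        t, q, qd, a, phi, u, u_syn, u_reg, forces, grf, stance, run_meta
    )
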