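"""Hill-type muscles with constant moment arms.

Each of the nine leg muscles is a contractile element (activation x
force-length x force-velocity) in parallel with a passive elastic element.
Because moment arms are constant, musculotendon length is affine in the
spanned joint angles,

    l = l_opt - sum_j r_j * (theta_j - theta_ref_j),

with ``r_j`` the signed moment arm (positive when the muscle produces a
flexion torque at joint *j*, the flexion-positive convention used throughout),
and the joint torque contribution is simply ``tau_j = r_j * F``.

Activation follows motor commands through a first-order low-pass filter with
separate rise and decay time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .motor_control import MUSCLES, N_MUSCLES

__all__ = [
    "HillCurves",
    "MuscleParameters",
    "MuscleSet",
    "activation_dynamics",
    "muscle_length",
    "force_length",
    "force_velocity",
    "contractile_force",
    "passive_force",
    "muscle_force",
    "joint_torques",
    "estimate_torques_from_emg",
]

JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class HillCurves:
    """Shape constants of the normalized Hill curves.

    ``fl_width``: Gaussian bell width of the force-length curve (in units of
    ``l_opt``); ``fv_shape``: curvature of the concentric hyperbola; ``fv_ecc``:
    eccentric force plateau (in units of ``F_max``).
    """

    fl_width: float = 0.45
    fv_shape: float = 0.25
    fv_ecc: float = 1.5
    pe_width: float = 0.50


@dataclass
class MuscleParameters:
    """One muscle: peak isometric force, optimal length, maximum shortening speed,
    signed constant moment arms, and passive-element slack length (l_opt units)."""

    name: str
    f_max: float
    l_opt: float
    v_max: float
    r_hip: float = 0.0
    r_knee: float = 0.0
    r_ankle: float = 0.0
    slack: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in MUSCLES:
            raise ValueError(f"unknown muscle {self.name!r}")
        if self.f_max <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ValueError("f_max, l_opt and v_max must be positive")

    @property
    def moment_arms(self) -> np.ndarray:
        return np.array([self.r_hip, self.r_knee, self.r_ankle])

    @property
    def n_joints(self) -> int:
        return int(np.count_nonzero(self.moment_arms))


@dataclass
class MuscleSet:
    """The nine muscles of one leg plus shared activation/curve constants.

    ``ref_angles`` is the (hip, knee, ankle) posture at which every muscle sits
    at its optimal length.
    """

    muscles: list[MuscleParameters]
    tau_rise: float = 0.02
    tau_fall: float = 0.06
    curves: HillCurves = field(default_factory=HillCurves)
    ref_angles: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.ref_angles = np.asarray(self.ref_angles, dtype=float)
        names = [m.name for m in self.muscles]
        if names != list(MUSCLES):
            raise ValueError(f"muscles must be exactly {MUSCLES} in order, got {names}")
        for m in self.muscles:
            expected = 2 if m.name in ("RF", "BFL", "GC") else 1
            if m.n_joints != expected:
                raise ValueError(
                    f"{m.name} must span {expected} joint(s), spans {m.n_joints}"
                )

    def __getitem__(self, name: str) -> MuscleParameters:
        return self.muscles[MUSCLES.index(name)]

    # -- packed views used by the compiled simulation engine ---------------
    def packed(self) -> tuple[np.ndarray, np.ndarray]:
        """(9, 7) per-muscle array [f_max, l_opt, v_max, r_hip, r_knee, r_ankle,
        slack] and (9,) scalar vector [tau_rise, tau_fall, fl_width, fv_shape,
        fv_ecc, pe_width, ref_hip, ref_knee, ref_ankle]."""
        arr = np.array(
            [
                [m.f_max, m.l_opt, m.v_max, m.r_hip, m.r_knee, m.r_ankle, m.slack]
                for m in self.muscles
            ]
        )
        c = self.curves
        scal = np.array(
            [self.tau_rise, self.tau_fall, c.fl_width, c.fv_shape, c.fv_ecc,
             c.pe_width, *self.ref_angles]
        )
        return arr, scal

    @classmethod
    def from_yaml(cls, path) -> "MuscleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        muscles = [MuscleParameters(name=n, **doc["muscles"][n]) for n in MUSCLES]
        curves = HillCurves(**doc.get("curves", {}))
        return cls(
            muscles=muscles,
            tau_rise=doc.get("tau_rise", 0.02),
            tau_fall=doc.get("tau_fall", 0.06),
            curves=curves,
            ref_angles=np.asarray(doc.get("ref_angles", [0.0, 0.0, 0.0])),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "tau_rise": float(self.tau_rise),
            "tau_fall": float(self.tau_fall),
            "curves": {
                "fl_width": self.curves.fl_width,
                "fv_shape": self.curves.fv_shape,
                "fv_ecc": self.curves.fv_ecc,
                "pe_width": self.curves.pe_width,
            },
            "ref_angles": [float(x) for x in self.ref_angles],
            "muscles": {
                m.name: {
                    "f_max": float(m.f_max),
                    "l_opt": float(m.l_opt),
                    "v_max": float(m.v_max),
                    "r_hip": float(m.r_hip),
                    "r_knee": float(m.r_knee),
                    "r_ankle": float(m.r_ankle),
                    "slack": float(m.slack),
                }
                for m in self.muscles
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def activation_dynamics(
    a: float, u: float, dt: float, tau_rise: float, tau_fall: float | None = None
) -> float:
    """One explicit-Euler step of the activation low-pass filter.

    ``da/dt = (clamp(u, 0, 1) - a) / tau`` with the rise constant when the
    drive exceeds the current activation and the (slower) decay constant
    otherwise.  The result is clamped to [0, 1].
    """
    if dt <= 0 or tau_rise <= 0:
        raise ValueError("dt and tau_rise must be positive")
    tau_fall = tau_rise if tau_fall is None else tau_fall
    uc = min(max(u, 0.0), 1.0)
    tau = tau_rise if uc >= a else tau_fall
    return float(np.clip(a + dt * (uc - a) / tau, 0.0, 1.0))


def muscle_length(
    joint_angles: np.ndarray,
    joint_rates: np.ndarray,
    mp: MuscleParameters,
    ref_angles: np.ndarray | None = None,
) -> tuple[float, float]:
    """Musculotendon length and lengthening rate from joint state.

    With constant moment arms the length is affine in the joint angles and the
    rate is exactly ``-sum_j r_j * theta_dot_j`` (no path-geometry terms).
    """
    ref = np.zeros(3) if ref_angles is None else np.asarray(ref_angles, dtype=float)
    r = mp.moment_arms
    l = mp.l_opt - float(r @ (np.asarray(joint_angles, dtype=float) - ref))
    l_dot = -float(r @ np.asarray(joint_rates, dtype=float))
    return l, l_dot


def force_length(l_norm, width: float = 0.45):
    """Gaussian bell ``exp(-((l/l_opt - 1)/width)^2)``; equals 1 at optimal length."""
    x = (np.asarray(l_norm, dtype=float) - 1.0) / width
    return np.exp(-x * x)


def force_velocity(v_norm, shape: float = 0.25, ecc: float = 1.5):
    """Hill force-velocity factor as a function of ``l_dot / v_max``.

    Negative argument = shortening: classic hyperbola reaching zero at the
    maximum shortening velocity.  Positive argument = lengthening: smooth
    continuation saturating at the eccentric plateau ``ecc``.  Equals 1 at
    zero velocity.
    """
    v = np.asarray(v_norm, dtype=float)
    conc = np.clip((1.0 + v) / (1.0 - v / shape), 0.0, None)
    eccf = ecc - (ecc - 1.0) * (1.0 - v) / (1.0 + 7.56 * v / shape)
    return np.where(v < 0.0, conc, eccf)


def contractile_force(
    a: float, l: float, l_dot: float, mp: MuscleParameters, curves: HillCurves = HillCurves()
) -> float:
    """Active force ``a * F_max * f_L(l/l_opt) * f_V(l_dot/v_max)`` (never negative)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    fl = force_length(l / mp.l_opt, curves.fl_width)
    fv = force_velocity(l_dot / mp.v_max, curves.fv_shape, curves.fv_ecc)
    return float(a * mp.f_max * fl * fv)


def passive_force(
    l: float, mp: MuscleParameters, curves: HillCurves = HillCurves()
) -> float:
    """Parallel-elastic force: zero at or below slack length, quadratic beyond."""
    strain = l / mp.l_opt - mp.slack
    if strain <= 0.0:
        return 0.0
    return float(mp.f_max * (strain / curves.pe_width) ** 2)


def muscle_force(
    a: float, l: float, l_dot: float, mp: MuscleParameters, curves: HillCurves = HillCurves()
) -> float:
    return contractile_force(a, l, l_dot, mp, curves) + passive_force(l, mp, curves)


def joint_torques(forces: np.ndarray, mset: MuscleSet) -> np.ndarray:
    """Map the nine muscle forces of one leg to (hip, knee, ankle) torques.

    ``tau_j = sum_m r_{m,j} * F_m`` with signed constant moment arms;
    positive torque flexes the joint.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.shape != (N_MUSCLES,):
        raise ValueError("expected one force per muscle")
    R = np.array([m.moment_arms for m in mset.muscles])  # (9, 3)
    return R.T @ forces


def estimate_torques_from_emg(
    joint_angles: np.ndarray,
    joint_rates: np.ndarray,
    activations: np.ndarray,
    mset: MuscleSet,
) -> np.ndarray:
    """Joint torques implied by measured kinematics and EMG envelopes.

    Treats the (scaled) EMG envelope of each muscle as its activation, derives
    muscle lengths and velocities from the joint-angle time series through the
    constant-moment-arm geometry, evaluates the Hill model and maps forces to
    (hip, knee, ankle) torques, sample by sample.

    Parameters are time-major: ``joint_angles``/``joint_rates`` with shape
    (n, 3) and ``activations`` with shape (n, 9).
    """
    q = np.atleast_2d(np.asarray(joint_angles, dtype=float))
    qd = np.atleast_2d(np.asarray(joint_rates, dtype=float))
    act = np.atleast_2d(np.asarray(activations, dtype=float))
    if not (q.shape[0] == qd.shape[0] == act.shape[0]):
        raise ValueError("time series lengths differ")
    if q.shape[1] != 3 or act.shape[1] != N_MUSCLES:
        raise ValueError("expected (n,3) kinematics and (n,9) activations")
    out = np.zeros((q.shape[0], 3))
    for k in range(q.shape[0]):
        forces = np.empty(N_MUSCLES)
        for j, mp in enumerate(mset.muscles):
            l, ld = muscle_length(q[k], qd[k], mp, mset.ref_angles)
            a = float(np.clip(act[k, j], 0.0, 1.0))
            forces[j] = muscle_force(a, l, ld, mp, mset.curves)
        out[k] = joint_torques(forces, mset)
    return out
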