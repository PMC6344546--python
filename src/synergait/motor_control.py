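"""Synergy-pulse motor commands and delayed feedback regulation.

The controller has two parts. A feedforward *movement generator* runs a phase
oscillator (``dphi/dt = 2*pi/T``) and emits five rectangular activation pulses
per gait cycle; each of the nine leg muscles receives a weighted sum of those
pulses (the muscle-synergy scheme).  A feedback *movement regulator* adds small
corrections for trunk-pitch balance (through the hip muscles IL/GM of the
standing leg) and for forward speed (through the ankle muscles TA/SO of the
standing leg), transmitted with a fixed neural delay ``tau``.

The left and right legs share one oscillator: one leg is driven at phase
``phi`` and the other at ``phi + pi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "MUSCLES",
    "PhaseState",
    "PulseParameters",
    "RegulatorParameters",
    "MotorCommand",
    "DelayLine",
    "advance_phase",
    "rectangular_pulse",
    "synergy_command",
    "trunk_regulator",
    "speed_regulator",
    "total_command",
    "regulator_contribution",
]

#: Muscle ordering used everywhere in the package.
#: IL iliopsoas (hip flexor), GM gluteus maximus (hip extensor),
#: VA vastii (knee extensor), BFS biceps femoris short head (knee flexor),
#: TA tibialis anterior (dorsiflexor), SO soleus (plantarflexor),
#: RF rectus femoris (hip flexor + knee extensor),
#: BFL biceps femoris long head (hip extensor + knee flexor),
#: GC gastrocnemius (knee flexor + plantarflexor).
MUSCLES: tuple[str, ...] = ("IL", "GM", "VA", "BFS", "TA", "SO", "RF", "BFL", "GC")
N_MUSCLES = len(MUSCLES)
N_PULSES = 5

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseState:
    """Oscillator phase ``phi`` in [0, 2*pi) and gait-cycle duration ``T`` (s)."""

    phi: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"gait cycle duration must be positive, got T={self.T}")
        self.phi = float(self.phi) % TWO_PI


@dataclass
class PulseParameters:
    """The 61 movement-generator parameters.

    ``T`` (s) cycle duration; ``onset[i]`` and ``duration[i]`` (rad) define the
    five rectangular pulses; ``weights[m, i]`` routes pulse *i* to muscle *m*
    (ordering :data:`MUSCLES`); ``amplitude[i]`` is the per-pulse gain tuned
    across gaits and speeds.
    """

    T: float
    onset: np.ndarray
    duration: np.ndarray
    weights: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.duration = np.asarray(self.duration, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.onset.shape != (N_PULSES,) or self.duration.shape != (N_PULSES,):
            raise ValueError("onset/duration must have shape (5,)")
        if self.weights.shape != (N_MUSCLES, N_PULSES):
            raise ValueError("weights must have shape (9, 5)")
        if self.amplitude.shape != (N_PULSES,):
            raise ValueError("amplitude must have shape (5,)")
        if np.any(self.duration <= 0):
            raise ValueError("pulse durations must be positive")
        if np.any(self.weights < 0) or np.any(self.amplitude < 0):
            raise ValueError("weights and amplitudes must be nonnegative")

    @property
    def n_free_parameters(self) -> int:
        """Total number of movement-generator parameters (T, 5 Phi, 5 Delta, 45 w, 5 Lambda)."""
        return 1 + N_PULSES + N_PULSES + self.weights.size + N_PULSES


@dataclass
class RegulatorParameters:
    """The 8 movement-regulator parameters plus the neural delay.

    Trunk loop (IL, GM): command ``-kappa_m*(theta - theta_ref) - sigma_m*theta_dot``
    during stance.  Speed loop (TA, SO): ``-lambda_m*(v - v_ref)`` during stance.
    ``tau`` (s) is the transmission delay of both loops.
    """

    kappa_IL: float = -1.0
    kappa_GM: float = 2.0
    sigma_IL: float = -0.2
    sigma_GM: float = 0.4
    lambda_TA: float = -0.2
    lambda_SO: float = 0.04
    theta_ref: float = 0.01
    v_ref: float = 1.6
    tau: float = 0.08

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("delay tau must be nonnegative")


@dataclass
class MotorCommand:
    """Per-muscle commands for one leg: synergy part, regulator part and total."""

    u_syn: np.ndarray
    u_reg: np.ndarray
    u: np.ndarray


def advance_phase(ps: PhaseState, dt: float) -> PhaseState:
    """Advance the oscillator by ``dt`` seconds: ``phi' = (phi + 2*pi*dt/T) mod 2*pi``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return PhaseState(phi=(ps.phi + TWO_PI * dt / ps.T) % TWO_PI, T=ps.T)


def rectangular_pulse(phi: float, onset: float, duration: float) -> float:
    """Rectangular pulse: 1 iff ``(phi - onset) mod 2*pi`` lies in ``(0, duration]``.

    The modular reading lets a pulse wrap past ``2*pi`` (the fifth preset pulse
    ends at 6.30 rad > 2*pi); the lower bound is strict, so ``phi == onset``
    returns 0.
    """
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    d = (phi - onset) % TWO_PI
    return 1.0 if 0.0 < d <= duration else 0.0


def _leg_phase(phi: float, leg: str) -> float:
    if leg == "right":
        return phi % TWO_PI
    if leg == "left":
        return (phi + np.pi) % TWO_PI
    raise ValueError(f"leg must be 'left' or 'right', got {leg!r}")


def synergy_command(
    ps: PhaseState, pp: PulseParameters, leg: Literal["left", "right"] = "right"
) -> np.ndarray:
    """Feedforward command ``u_syn[m] = sum_i Lambda_i * w[m,i] * p_i(phi_leg)``.

    The right leg runs at phase ``phi``, the left leg at ``phi + pi``.
    """
    phil = _leg_phase(ps.phi, leg)
    p = np.array(
        [rectangular_pulse(phil, pp.onset[i], pp.duration[i]) for i in range(N_PULSES)]
    )
    return pp.weights @ (pp.amplitude * p)


def trunk_regulator(
    theta: float, theta_dot: float, in_stance: bool, rp: RegulatorParameters
) -> np.ndarray:
    """Trunk-balance pre-command: nonzero only for IL and GM of a stance leg."""
    p = np.zeros(N_MUSCLES)
    if in_stance:
        err = theta - rp.theta_ref
        p[MUSCLES.index("IL")] = -rp.kappa_IL * err - rp.sigma_IL * theta_dot
        p[MUSCLES.index("GM")] = -rp.kappa_GM * err - rp.sigma_GM * theta_dot
    return p


def speed_regulator(v: float, in_stance: bool, rp: RegulatorParameters) -> np.ndarray:
    """Speed pre-command: nonzero only for TA and SO of a stance leg."""
    p = np.zeros(N_MUSCLES)
    if in_stance:
        err = v - rp.v_ref
        p[MUSCLES.index("TA")] = -rp.lambda_TA * err
        p[MUSCLES.index("SO")] = -rp.lambda_SO * err
    return p


class DelayLine:
    """Ring buffer implementing the neural transmission delay.

    Pre-commands are pushed once per control step; a query at time ``t``
    returns the sample recorded nearest to ``t - tau`` (zero before one delay
    horizon has elapsed).
    """

    def __init__(self, tau: float, dt: float, width: int = N_MUSCLES):
        if tau < 0 or dt <= 0:
            raise ValueError("need tau >= 0 and dt > 0")
        self.tau = tau
        self.dt = dt
        self.n_delay = int(round(tau / dt))
        self.width = width
        self._buf = np.zeros((self.n_delay + 1, width))
        self._idx = 0  # number of samples pushed so far

    def push(self, sample: np.ndarray) -> None:
        sample = np.asarray(sample, dtype=float)
        if sample.shape != (self.width,):
            raise ValueError("sample width mismatch")
        self._buf[self._idx % self._buf.shape[0]] = sample
        self._idx += 1

    def delayed(self) -> np.ndarray:
        """Sample recorded ``tau`` before the most recent push (zeros during
        the initial horizon)."""
        if self._idx == 0:
            raise ValueError("delay line is empty")
        k = self._idx - 1 - self.n_delay
        if k < 0:
            return np.zeros(self.width)
        return self._buf[k % self._buf.shape[0]].copy()


def delayed_regulator(t: float, dl: DelayLine, tau: float | None = None) -> np.ndarray:
    """Regulator command ``u_reg(t) = p_trunk(t - tau) + p_speed(t - tau)``.

    ``dl`` must hold the summed pre-commands sampled on the control grid up to
    time ``t``; returns zeros for ``t`` earlier than one delay horizon.
    """
    tau = dl.tau if tau is None else tau
    if t < tau - 0.5 * dl.dt:
        return np.zeros(dl.width)
    return dl.delayed()


def total_command(
    u_syn: np.ndarray, u_reg: np.ndarray, u_max: float = 1.5
) -> np.ndarray:
    """Motor output ``u = u_syn + u_reg`` clamped to ``[0, u_max]``.

    Motor-neuron drive cannot be negative, so a regulator correction may at
    most silence a muscle; the upper clamp bounds the drive fed to the
    activation filter.
    """
    return np.clip(np.asarray(u_syn) + np.asarray(u_reg), 0.0, u_max)


def regulator_contribution(
    u: np.ndarray,
    u_reg: np.ndarray,
    mode: str = "all",
) -> float:
    """Percent share of the feedback regulator in the total motor commands.

    Computed as ``100 * integral(sum_m |u_reg|) / integral(sum_m |u|)`` over the
    supplied samples (uniform sampling assumed, so plain sums suffice).

    ``mode`` selects which muscles enter the sums: ``"all"`` (default) uses all
    nine muscles in both numerator and denominator; ``"speed"`` restricts the
    numerator to the TA/SO speed loop; ``"taso"`` restricts both sums to TA/SO.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    u_reg = np.atleast_2d(np.asarray(u_reg, dtype=float))
    if u.shape != u_reg.shape:
        raise ValueError("u and u_reg must have identical shapes")
    ncol = u.shape[1]
    ta_so = [i for i in range(ncol) if i % N_MUSCLES in (MUSCLES.index("TA"), MUSCLES.index("SO"))]
    if mode == "all":
        num = np.abs(u_reg).sum()
        den = np.abs(u).sum()
    elif mode == "speed":
        num = np.abs(u_reg[:, ta_so]).sum()
        den = np.abs(u).sum()
    elif mode == "taso":
        num = np.abs(u_reg[:, ta_so]).sum()
        den = np.abs(u[:, ta_so]).sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        raise ValueError("total command integral is zero")
    return 100.0 * float(num) / float(den)
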