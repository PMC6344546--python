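"""Independent reference implementations used by the test suite.

The equations-of-motion oracle derives the planar seven-link dynamics from
the Lagrangian with sympy — symbolic differentiation of the segment
kinematics, entirely independent of the package's numeric Jacobian assembly —
and returns a callable for the mass matrix and forcing vector.
"""

from __future__ import annotations

import numpy as np
import sympy as sp


def build_lagrangian_oracle(body):
    """Return ``f(q, qd) -> (M, h)`` with ``M qdd = h`` for the unforced
    skeleton (gravity only; no muscles, viscosity, limits or contact).

    Uses ``M = Hessian_qd(KE)`` and
    ``h_i = -sum_j d2L/(dqd_i dq_j) qd_j + dL/dq_i`` (Lagrange's equations
    with the qdd terms moved to the left).
    """
    qs = sp.symbols("q0:9")
    qds = sp.symbols("qd0:9")
    x, y, th = qs[0], qs[1], qs[2]
    g = sp.Float(body.g)

    def vel(expr):
        return sum(sp.diff(expr, qs[j]) * qds[j] for j in range(9))

    segments = []  # (px, py, ang, m, I)
    segments.append((x, y, th, body.m_trunk, body.i_trunk))
    hx = x + body.d_hip * sp.sin(th)
    hy = y - body.d_hip * sp.cos(th)
    for b in (3, 6):
        psi1 = th + qs[b]
        psi2 = psi1 - qs[b + 1]
        chi = psi2 + sp.pi / 2 + qs[b + 2]
        segments.append(
            (hx + body.c_thigh * sp.sin(psi1), hy - body.c_thigh * sp.cos(psi1),
             psi1, body.m_thigh, body.i_thigh)
        )
        kx = hx + body.l_thigh * sp.sin(psi1)
        ky = hy - body.l_thigh * sp.cos(psi1)
        segments.append(
            (kx + body.c_shank * sp.sin(psi2), ky - body.c_shank * sp.cos(psi2),
             psi2, body.m_shank, body.i_shank)
        )
        ax = kx + body.l_shank * sp.sin(psi2)
        ay = ky - body.l_shank * sp.cos(psi2)
        segments.append(
            (ax + body.c_foot_ax * sp.sin(chi) - body.c_foot_pp * sp.cos(chi),
             ay - body.c_foot_ax * sp.cos(chi) - body.c_foot_pp * sp.sin(chi),
             chi, body.m_foot, body.i_foot)
        )

    KE = sp.S.Zero
    PE = sp.S.Zero
    for px, py, ang, m, inertia in segments:
        vx, vy, w = vel(px), vel(py), vel(ang)
        KE += sp.Rational(1, 2) * m * (vx**2 + vy**2) + sp.Rational(1, 2) * inertia * w**2
        PE += m * g * py
    L = KE - PE

    dLdqd = [sp.diff(L, qds[i]) for i in range(9)]
    Msym = sp.Matrix(9, 9, lambda i, j: sp.diff(dLdqd[i], qds[j]))
    hsym = sp.Matrix(
        9,
        1,
        lambda i, _: sp.diff(L, qs[i])
        - sum(sp.diff(dLdqd[i], qs[j]) * qds[j] for j in range(9)),
    )

    fM = sp.lambdify((qs, qds), Msym, modules="numpy", cse=True)
    fh = sp.lambdify((qs, qds), hsym, modules="numpy", cse=True)

    def oracle(q, qd):
        M = np.asarray(fM(tuple(q), tuple(qd)), dtype=float)
        h = np.asarray(fh(tuple(q), tuple(qd)), dtype=float).ravel()
        return M, h

    return oracle
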