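"""Compiled inner loop of the forward-dynamics simulator.

Everything here operates on packed float64 arrays so it can be jit-compiled
with numba.  The friendly, typed surface lives in :mod:`skeleton_dynamics`,
:mod:`muscle_model` and :mod:`motor_control`; those modules and the tests
treat this file as the single source of the hot physics.

Conventions
-----------
Generalized coordinates ``q = (x, y, theta, hipR, kneeR, ankleR, hipL, kneeL,
ankleL)``: trunk-COM translation, trunk pitch (CCW-positive, so positive
theta is a backward lean when travelling along +x) and flexion-positive joint
angles.  The equations of motion are assembled from segment Jacobians,

    M(q) = sum_s [ m_s J_s^T J_s + I_s jw_s jw_s^T ],
    M qdd = h(q, qd) + Q,   h = -sum_s m_s J_s^T a0_s - dV/dq,

where ``a0_s`` is the segment-COM acceleration at ``qdd = 0`` (planar chains
make the rotational bias vanish because segment angles are linear in q).

Body-parameter packing (length 35)::

    0 m_trunk  1 I_trunk  2 d_hip    3 m_thigh 4 I_thigh 5 L_thigh 6 c_thigh
    7 m_shank  8 I_shank  9 L_shank 10 c_shank 11 m_foot 12 I_foot
    13 c_foot_ax 14 c_foot_pp 15 h_sole 16:20 sole point offsets (from ankle)
    20 k_n 21 c_n 22 k_t 23 c_t 24 mu 25 g
    26 c_hip 27 c_knee 28 c_ankle 29 knee_lo 30 knee_hi 31 ankle_lo
    32 ankle_hi 33 k_lim 34 c_lim

Muscle packing: ``mp`` (9, 7) rows ``[f_max, l_opt, v_max, r_hip, r_knee,
r_ankle, slack]``; ``msc`` (9,) ``[tau_rise, tau_fall, fl_width, fv_shape,
fv_ecc, pe_width, ref_hip, ref_knee, ref_ankle]``.

Control packing (length 71)::

    0 T  1:6 Phi  6:11 Delta  11:16 Lambda  16:61 w (muscle-major, 9x5)
    61 kappa_IL 62 kappa_GM 63 sigma_IL 64 sigma_GM 65 lambda_TA 66 lambda_SO
    67 theta_ref 68 v_ref 69 tau 70 u_max

State vector ``y`` (37): ``q`` (9), ``qd`` (9), activations (18: right leg
muscles 0..8, left 9..17), oscillator phase (1).
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi

# muscle indices (order IL GM VA BFS TA SO RF BFL GC)
I_IL, I_GM, I_VA, I_BFS, I_TA, I_SO, I_RF, I_BFL, I_GC = range(9)

# status codes returned by the loop
OK = 0
FELL = 1
DIVERGED = 2


@njit(cache=False)
def kin_eom(q, qd, bp):
    """Mass matrix, bias vector and sole-point kinematics at one state.

    Returns ``(M, h, sole_pos, sole_vel, sole_J)`` with sole arrays shaped
    (2 legs, 4 points, ...); ``sole_J`` is (2, 4, 2, 9).
    """
    M = np.zeros((9, 9))
    h = np.zeros(9)
    sole_pos = np.zeros((2, 4, 2))
    sole_vel = np.zeros((2, 4, 2))
    sole_J = np.zeros((2, 4, 2, 9))

    g = bp[25]
    x = q[0]
    y = q[1]
    th = q[2]
    xd = qd[0]
    yd = qd[1]
    thd = qd[2]

    # trunk segment: COM is (x, y), world angle = theta
    m_t = bp[0]
    M[0, 0] += m_t
    M[1, 1] += m_t
    M[2, 2] += bp[1]
    h[1] += -m_t * g

    sinth = math.sin(th)
    costh = math.cos(th)
    d_hip = bp[2]

    # hip point shared by both legs
    hx = x + d_hip * sinth
    hy = y - d_hip * costh
    vhx = xd + d_hip * costh * thd
    vhy = yd + d_hip * sinth * thd
    a0hx = -d_hip * sinth * thd * thd
    a0hy = d_hip * costh * thd * thd
    jh_th_x = d_hip * costh
    jh_th_y = d_hip * sinth

    Jx = np.zeros(9)
    Jy = np.zeros(9)
    jw = np.zeros(9)

    for leg in range(2):
        b = 3 + 3 * leg

        # --- thigh --------------------------------------------------------
        psi1 = th + q[b]
        psid1 = thd + qd[b]
        s1 = math.sin(psi1)
        c1 = math.cos(psi1)

        c_th = bp[6]
        L_th = bp[5]

        # thigh COM
        Jx[:] = 0.0
        Jy[:] = 0.0
        Jx[0] = 1.0
        Jy[1] = 1.0
        Jx[2] = jh_th_x + c_th * c1
        Jy[2] = jh_th_y + c_th * s1
        Jx[b] = c_th * c1
        Jy[b] = c_th * s1
        a0x = a0hx - c_th * s1 * psid1 * psid1
        a0y = a0hy + c_th * c1 * psid1 * psid1
        jw[:] = 0.0
        jw[2] = 1.0
        jw[b] = 1.0
        _accumulate(M, h, Jx, Jy, jw, bp[3], bp[4], a0x, a0y, g)

        # knee point
        kx = hx + L_th * s1
        ky = hy - L_th * c1
        vkx = vhx + L_th * c1 * psid1
        vky = vhy + L_th * s1 * psid1
        a0kx = a0hx - L_th * s1 * psid1 * psid1
        a0ky = a0hy + L_th * c1 * psid1 * psid1
        jk_th_x = jh_th_x + L_th * c1
        jk_th_y = jh_th_y + L_th * s1
        jk_b_x = L_th * c1
        jk_b_y = L_th * s1

        # --- shank --------------------------------------------------------
        psi2 = psi1 - q[b + 1]
        psid2 = psid1 - qd[b + 1]
        s2 = math.sin(psi2)
        c2 = math.cos(psi2)
        c_sh = bp[10]
        L_sh = bp[9]

        Jx[:] = 0.0
        Jy[:] = 0.0
        Jx[0] = 1.0
        Jy[1] = 1.0
        Jx[2] = jk_th_x + c_sh * c2
        Jy[2] = jk_th_y + c_sh * s2
        Jx[b] = jk_b_x + c_sh * c2
        Jy[b] = jk_b_y + c_sh * s2
        Jx[b + 1] = -c_sh * c2
        Jy[b + 1] = -c_sh * s2
        a0x = a0kx - c_sh * s2 * psid2 * psid2
        a0y = a0ky + c_sh * c2 * psid2 * psid2
        jw[:] = 0.0
        jw[2] = 1.0
        jw[b] = 1.0
        jw[b + 1] = -1.0
        _accumulate(M, h, Jx, Jy, jw, bp[7], bp[8], a0x, a0y, g)

        # ankle point
        ax = kx + L_sh * s2
        ay = ky - L_sh * c2
        vax = vkx + L_sh * c2 * psid2
        vay = vky + L_sh * s2 * psid2
        a0ax = a0kx - L_sh * s2 * psid2 * psid2
        a0ay = a0ky + L_sh * c2 * psid2 * psid2
        ja_th_x = jk_th_x + L_sh * c2
        ja_th_y = jk_th_y + L_sh * s2
        ja_b_x = jk_b_x + L_sh * c2
        ja_b_y = jk_b_y + L_sh * s2
        ja_b1_x = -L_sh * c2
        ja_b1_y = -L_sh * s2

        # --- foot ---------------------------------------------------------
        chi = psi2 + 0.5 * math.pi + q[b + 2]
        chid = psid2 + qd[b + 2]
        sc = math.sin(chi)
        cc = math.cos(chi)
        # foot axis f = (sc, -cc), downward normal n = (-cc, -sc)
        # offset o(ax_off, pp_off) = ax_off*f + pp_off*n
        # d(o)/d(chi) = ax_off*(cc, sc) + pp_off*(sc, -cc)

        c_fax = bp[13]
        c_fpp = bp[14]
        ox = c_fax * sc - c_fpp * cc
        oy = -c_fax * cc - c_fpp * sc
        dox = c_fax * cc + c_fpp * sc
        doy = c_fax * sc - c_fpp * cc

        Jx[:] = 0.0
        Jy[:] = 0.0
        Jx[0] = 1.0
        Jy[1] = 1.0
        Jx[2] = ja_th_x + dox
        Jy[2] = ja_th_y + doy
        Jx[b] = ja_b_x + dox
        Jy[b] = ja_b_y + doy
        Jx[b + 1] = ja_b1_x - dox
        Jy[b + 1] = ja_b1_y - doy
        Jx[b + 2] = dox
        Jy[b + 2] = doy
        a0x = a0ax - chid * chid * ox
        a0y = a0ay - chid * chid * oy
        jw[:] = 0.0
        jw[2] = 1.0
        jw[b] = 1.0
        jw[b + 1] = -1.0
        jw[b + 2] = 1.0
        _accumulate(M, h, Jx, Jy, jw, bp[11], bp[12], a0x, a0y, g)

        # sole contact points
        h_sole = bp[15]
        for i in range(4):
            s_i = bp[16 + i]
            pox = s_i * sc - h_sole * cc
            poy = -s_i * cc - h_sole * sc
            pdox = s_i * cc + h_sole * sc
            pdoy = s_i * sc - h_sole * cc
            sole_pos[leg, i, 0] = ax + pox
            sole_pos[leg, i, 1] = ay + poy
            sole_vel[leg, i, 0] = vax + chid * pdox
            sole_vel[leg, i, 1] = vay + chid * pdoy
            sole_J[leg, i, 0, 0] = 1.0
            sole_J[leg, i, 1, 1] = 1.0
            sole_J[leg, i, 0, 2] = ja_th_x + pdox
            sole_J[leg, i, 1, 2] = ja_th_y + pdoy
            sole_J[leg, i, 0, b] = ja_b_x + pdox
            sole_J[leg, i, 1, b] = ja_b_y + pdoy
            sole_J[leg, i, 0, b + 1] = ja_b1_x - pdox
            sole_J[leg, i, 1, b + 1] = ja_b1_y - pdoy
            sole_J[leg, i, 0, b + 2] = pdox
            sole_J[leg, i, 1, b + 2] = pdoy

    return M, h, sole_pos, sole_vel, sole_J


@njit(cache=False)
def _accumulate(M, h, Jx, Jy, jw, m, inertia, a0x, a0y, g):
    for i in range(9):
        jxi = Jx[i]
        jyi = Jy[i]
        jwi = jw[i]
        if jxi == 0.0 and jyi == 0.0 and jwi == 0.0:
            continue
        for j in range(i, 9):
            val = m * (jxi * Jx[j] + jyi * Jy[j]) + inertia * jwi * jw[j]
            M[i, j] += val
            if j != i:
                M[j, i] += val
        h[i] += -m * (jxi * a0x + jyi * a0y) - m * g * jyi


@njit(cache=False)
def contact_forces(sole_pos, sole_vel, anchors, active, bp):
    """Viscoelastic sole forces, (2, 4, 2): unilateral normal spring-damper
    plus anchored tangential spring-damper capped by ``mu * F_n``."""
    f = np.zeros((2, 4, 2))
    k_n = bp[20]
    c_n = bp[21]
    k_t = bp[22]
    c_t = bp[23]
    mu = bp[24]
    for leg in range(2):
        for i in range(4):
            py = sole_pos[leg, i, 1]
            if py >= 0.0:
                continue
            vy = sole_vel[leg, i, 1]
            fn = -k_n * py - c_n * vy
            if fn < 0.0:
                fn = 0.0
            ft = 0.0
            if active[leg, i] == 1:
                ft = -k_t * (sole_pos[leg, i, 0] - anchors[leg, i]) - c_t * sole_vel[leg, i, 0]
                cap = mu * fn
                if ft > cap:
                    ft = cap
                elif ft < -cap:
                    ft = -cap
            f[leg, i, 0] = ft
            f[leg, i, 1] = fn
    return f


@njit(cache=False)
def update_anchors(sole_pos, sole_vel, anchors, active, bp):
    """Discrete per-step anchor bookkeeping: engage at touchdown, release at
    liftoff, and let the anchor slip so the elastic tangential force never
    exceeds the friction cone."""
    k_n = bp[20]
    c_n = bp[21]
    k_t = bp[22]
    mu = bp[24]
    for leg in range(2):
        for i in range(4):
            py = sole_pos[leg, i, 1]
            if py >= 0.0:
                active[leg, i] = 0
                continue
            px = sole_pos[leg, i, 0]
            if active[leg, i] == 0:
                active[leg, i] = 1
                anchors[leg, i] = px
            else:
                fn = -k_n * py - c_n * sole_vel[leg, i, 1]
                if fn < 0.0:
                    fn = 0.0
                ft_el = -k_t * (px - anchors[leg, i])
                cap = mu * fn
                if ft_el > cap:
                    anchors[leg, i] = px + cap / k_t
                elif ft_el < -cap:
                    anchors[leg, i] = px - cap / k_t


@njit(cache=False)
def muscle_torques(q, qd, act, mp, msc):
    """Muscle forces (18,) and joint torques (6: hipR kneeR ankleR hipL kneeL
    ankleL) from the Hill model with constant moment arms."""
    forces = np.zeros(18)
    tau = np.zeros(6)
    fl_w = msc[2]
    fv_k = msc[3]
    fv_n = msc[4]
    pe_w = msc[5]
    for leg in range(2):
        b = 3 + 3 * leg
        dth_h = q[b] - msc[6]
        dth_k = q[b + 1] - msc[7]
        dth_a = q[b + 2] - msc[8]
        for m in range(9):
            f_max = mp[m, 0]
            l_opt = mp[m, 1]
            v_max = mp[m, 2]
            r_h = mp[m, 3]
            r_k = mp[m, 4]
            r_a = mp[m, 5]
            slack = mp[m, 6]
            ln = 1.0 - (r_h * dth_h + r_k * dth_k + r_a * dth_a) / l_opt
            ld = -(r_h * qd[b] + r_k * qd[b + 1] + r_a * qd[b + 2])
            xfl = (ln - 1.0) / fl_w
            fl = math.exp(-xfl * xfl)
            vn = ld / v_max
            if vn < 0.0:
                if vn <= -1.0:
                    fv = 0.0
                else:
                    fv = (1.0 + vn) / (1.0 - vn / fv_k)
            else:
                fv = fv_n - (fv_n - 1.0) * (1.0 - vn) / (1.0 + 7.56 * vn / fv_k)
            a = act[9 * leg + m]
            fce = a * f_max * fl * fv
            strain = ln - slack
            fpe = 0.0
            if strain > 0.0:
                fpe = f_max * (strain / pe_w) * (strain / pe_w)
            F = fce + fpe
            if F < 0.0:
                F = 0.0
            forces[9 * leg + m] = F
            tau[3 * leg] += r_h * F
            tau[3 * leg + 1] += r_k * F
            tau[3 * leg + 2] += r_a * F
    return forces, tau


@njit(cache=False)
def passive_joint_torques(q, qd, bp):
    """Linear joint viscosity plus stiff spring-damper joint limits (knee, ankle)."""
    tau = np.zeros(6)
    k_lim = bp[33]
    c_lim = bp[34]
    for leg in range(2):
        b = 3 + 3 * leg
        tau[3 * leg] += -bp[26] * qd[b]
        tau[3 * leg + 1] += -bp[27] * qd[b + 1]
        tau[3 * leg + 2] += -bp[28] * qd[b + 2]
        # knee limits
        kq = q[b + 1]
        if kq > bp[30]:
            tau[3 * leg + 1] += -k_lim * (kq - bp[30]) - c_lim * qd[b + 1]
        elif kq < bp[29]:
            tau[3 * leg + 1] += -k_lim * (kq - bp[29]) - c_lim * qd[b + 1]
        aq = q[b + 2]
        if aq > bp[32]:
            tau[3 * leg + 2] += -k_lim * (aq - bp[32]) - c_lim * qd[b + 2]
        elif aq < bp[31]:
            tau[3 * leg + 2] += -k_lim * (aq - bp[31]) - c_lim * qd[b + 2]
    return tau


@njit(cache=False)
def deriv(y, u, anchors, active, bp, mp, msc, T, tau_rise, tau_fall):
    """Time derivative of the packed state with the motor command held fixed."""
    q = y[0:9]
    qd = y[9:18]
    act = y[18:36]

    M, h, sp, sv, sJ = kin_eom(q, qd, bp)
    f = contact_forces(sp, sv, anchors, active, bp)
    forces, tau_m = muscle_torques(q, qd, act, mp, msc)
    tau_p = passive_joint_torques(q, qd, bp)

    Q = np.zeros(9)
    for leg in range(2):
        b = 3 + 3 * leg
        for j in range(3):
            Q[b + j] += tau_m[3 * leg + j] + tau_p[3 * leg + j]
        for i in range(4):
            fx = f[leg, i, 0]
            fy = f[leg, i, 1]
            if fx == 0.0 and fy == 0.0:
                continue
            for k in range(9):
                Q[k] += sJ[leg, i, 0, k] * fx + sJ[leg, i, 1, k] * fy

    qdd = np.linalg.solve(M, h + Q)

    dy = np.empty(37)
    dy[0:9] = qd
    dy[9:18] = qdd
    for m in range(18):
        uc = u[m]
        if uc > 1.0:
            uc = 1.0
        elif uc < 0.0:
            uc = 0.0
        a = act[m]
        tau_a = tau_rise if uc >= a else tau_fall
        dy[18 + m] = (uc - a) / tau_a
    dy[36] = TWO_PI / T
    return dy


@njit(cache=False)
def synergy_commands(phi, ctrl, u_syn):
    """Fill u_syn (18,): right leg at phase phi, left leg at phi + pi."""
    for leg in range(2):
        phil = (phi + math.pi * leg) % TWO_PI
        for m in range(9):
            u_syn[9 * leg + m] = 0.0
        for i in range(5):
            d = (phil - ctrl[1 + i]) % TWO_PI
            if 0.0 < d <= ctrl[6 + i]:
                lam = ctrl[11 + i]
                for m in range(9):
                    w = ctrl[16 + 5 * m + i]
                    if w > 0.0:
                        u_syn[9 * leg + m] += lam * w


@njit(cache=False)
def simulate_loop(
    y0,
    anchors,
    active,
    bp,
    mp,
    msc,
    ctrl,
    dt,
    n_steps,
    decim,
    y_fall,
    th_fall,
    stance_thresh,
    debounce,
):
    """Integrate the closed loop for ``n_steps`` of size ``dt``.

    Records every ``decim``-th step.  Returns the filled output arrays, the
    number of recorded samples, touchdown/liftoff event lists, and a status
    code (OK / FELL / DIVERGED) with the time of the last valid state.
    """
    n_out = n_steps // decim + 1
    t_out = np.zeros(n_out)
    q_out = np.zeros((n_out, 9))
    qd_out = np.zeros((n_out, 9))
    a_out = np.zeros((n_out, 18))
    phi_out = np.zeros(n_out)
    u_out = np.zeros((n_out, 18))
    usyn_out = np.zeros((n_out, 18))
    ureg_out = np.zeros((n_out, 18))
    f_out = np.zeros((n_out, 18))
    grf_out = np.zeros((n_out, 4))
    stance_out = np.zeros((n_out, 2))

    max_ev = 4000
    td_time = np.zeros(max_ev)
    td_leg = np.zeros(max_ev, dtype=np.int64)
    n_td = 0
    lo_time = np.zeros(max_ev)
    lo_leg = np.zeros(max_ev, dtype=np.int64)
    n_lo = 0

    T = ctrl[0]
    tau_delay = ctrl[69]
    u_max = ctrl[70]
    tau_rise = msc[0]
    tau_fall = msc[1]

    n_delay = int(round(tau_delay / dt))
    buf_size = n_delay if n_delay > 0 else 1
    buf = np.zeros((buf_size, 8))

    y = y0.copy()
    u = np.zeros(18)
    u_syn = np.zeros(18)
    u_reg = np.zeros(18)
    pre = np.zeros(8)

    stance_prev = np.zeros(2, dtype=np.int64)
    last_ev = np.zeros(2)
    last_ev[0] = -1.0
    last_ev[1] = -1.0

    status = OK
    n_rec = 0
    t = 0.0
    i = 0
    while i < n_steps:
        q = y[0:9]
        qd = y[9:18]

        if not (np.isfinite(y).all()):
            status = DIVERGED
            break

        M, h, sp, sv, sJ = kin_eom(q, qd, bp)
        update_anchors(sp, sv, anchors, active, bp)
        f = contact_forces(sp, sv, anchors, active, bp)

        grf_r_x = f[0, :, 0].sum()
        grf_r_y = f[0, :, 1].sum()
        grf_l_x = f[1, :, 0].sum()
        grf_l_y = f[1, :, 1].sum()

        stance0 = 1 if grf_r_y > stance_thresh else 0
        stance1 = 1 if grf_l_y > stance_thresh else 0

        # touchdown / liftoff events with debounce
        for leg in range(2):
            s_now = stance0 if leg == 0 else stance1
            if s_now != stance_prev[leg] and (t - last_ev[leg]) > debounce:
                if s_now == 1:
                    if n_td < max_ev:
                        td_time[n_td] = t
                        td_leg[n_td] = leg
                        n_td += 1
                else:
                    if n_lo < max_ev:
                        lo_time[n_lo] = t
                        lo_leg[n_lo] = leg
                        n_lo += 1
                last_ev[leg] = t
                stance_prev[leg] = s_now

        # fall detection
        if q[1] < y_fall or abs(q[2]) > th_fall:
            status = FELL
            break

        # ---- control sampled on the integrator grid ----------------------
        phi = y[36]
        synergy_commands(phi, ctrl, u_syn)

        theta = q[2]
        thetad = qd[2]
        v = qd[0]
        for leg in range(2):
            s_now = stance0 if leg == 0 else stance1
            if s_now == 1:
                err = theta - ctrl[67]
                pre[4 * leg + 0] = -ctrl[61] * err - ctrl[63] * thetad  # IL
                pre[4 * leg + 1] = -ctrl[62] * err - ctrl[64] * thetad  # GM
                verr = v - ctrl[68]
                pre[4 * leg + 2] = -ctrl[65] * verr  # TA
                pre[4 * leg + 3] = -ctrl[66] * verr  # SO
            else:
                pre[4 * leg + 0] = 0.0
                pre[4 * leg + 1] = 0.0
                pre[4 * leg + 2] = 0.0
                pre[4 * leg + 3] = 0.0

        if n_delay == 0:
            delayed = pre
        elif i >= n_delay:
            delayed = buf[(i - n_delay) % buf_size]
        else:
            delayed = np.zeros(8)
        if n_delay > 0:
            buf[i % buf_size] = pre

        for m in range(18):
            u_reg[m] = 0.0
        for leg in range(2):
            u_reg[9 * leg + I_IL] = delayed[4 * leg + 0]
            u_reg[9 * leg + I_GM] = delayed[4 * leg + 1]
            u_reg[9 * leg + I_TA] = delayed[4 * leg + 2]
            u_reg[9 * leg + I_SO] = delayed[4 * leg + 3]

        for m in range(18):
            val = u_syn[m] + u_reg[m]
            if val < 0.0:
                val = 0.0
            elif val > u_max:
                val = u_max
            u[m] = val

        # ---- record -------------------------------------------------------
        if i % decim == 0:
            forces, _ = muscle_torques(q, qd, y[18:36], mp, msc)
            t_out[n_rec] = t
            q_out[n_rec] = q
            qd_out[n_rec] = qd
            a_out[n_rec] = y[18:36]
            phi_out[n_rec] = phi % TWO_PI
            u_out[n_rec] = u
            usyn_out[n_rec] = u_syn
            ureg_out[n_rec] = u_reg
            f_out[n_rec] = forces
            grf_out[n_rec, 0] = grf_r_x
            grf_out[n_rec, 1] = grf_r_y
            grf_out[n_rec, 2] = grf_l_x
            grf_out[n_rec, 3] = grf_l_y
            stance_out[n_rec, 0] = stance0
            stance_out[n_rec, 1] = stance1
            n_rec += 1

        # ---- RK4 ----------------------------------------------------------
        k1 = deriv(y, u, anchors, active, bp, mp, msc, T, tau_rise, tau_fall)
        k2 = deriv(y + 0.5 * dt * k1, u, anchors, active, bp, mp, msc, T, tau_rise, tau_fall)
        k3 = deriv(y + 0.5 * dt * k2, u, anchors, active, bp, mp, msc, T, tau_rise, tau_fall)
        k4 = deriv(y + dt * k3, u, anchors, active, bp, mp, msc, T, tau_rise, tau_fall)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        i += 1
        t = i * dt

    return (
        t_out[:n_rec],
        q_out[:n_rec],
        qd_out[:n_rec],
        a_out[:n_rec],
        phi_out[:n_rec],
        u_out[:n_rec],
        usyn_out[:n_rec],
        ureg_out[:n_rec],
        f_out[:n_rec],
        grf_out[:n_rec],
        stance_out[:n_rec],
        td_time[:n_td],
        td_leg[:n_td],
        lo_time[:n_lo],
        lo_leg[:n_lo],
        status,
        t,
        y,
    )
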