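"""Numba-compiled numerical core.

Everything in this module operates on flat NumPy arrays so it can be JIT
compiled.  Higher-level modules (`biomech`, `engine`) build these arrays from
their parameter objects and wrap the kernels in a friendly API.

Plant state vector layout (length 28)::

    y[0:2]    joint angles (shoulder, elbow)          [rad]
    y[2:4]    joint velocities                        [rad/s]
    y[4:10]   muscle tensions T                       [N]
    y[10:16]  static bag-fiber tensions T_s           [N]
    y[16:22]  dynamic bag-fiber tensions T_d          [N]
    y[22:28]  Ib (GTO) low-pass filter states         [dimensionless rate]
"""

import numpy as np
from numba import njit

NY = 28  # plant state size


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@njit(cache=True)
def chord_geometry(q1, q2, pframe, pxy, L1):
    """Straight-line (chord) muscle lengths and moment arms.

    pframe : (6, 2) int    frame of each endpoint (0 torso, 1 upper arm, 2 forearm)
    pxy    : (6, 2, 2)     endpoint coordinates in their local frame

    Returns (lengths(6), dldq(6, 2)) with dldq[m, j] = dL_m/dq_j.  Used to
    calibrate the rest lengths and rest moment arms; the simulated path is
    the pulley model below, which agrees with the chord at the rest posture.
    """
    c1, s1 = np.cos(q1), np.sin(q1)
    c12, s12 = np.cos(q1 + q2), np.sin(q1 + q2)
    ex, ey = L1 * c1, L1 * s1  # elbow position

    lengths = np.empty(6)
    dldq = np.empty((6, 2))
    for m in range(6):
        pw = np.empty((2, 2))   # world coords of the two endpoints
        for k in range(2):
            fx, fy = pxy[m, k, 0], pxy[m, k, 1]
            fr = pframe[m, k]
            if fr == 0:
                pw[k, 0], pw[k, 1] = fx, fy
            elif fr == 1:
                pw[k, 0] = c1 * fx - s1 * fy
                pw[k, 1] = s1 * fx + c1 * fy
            else:
                pw[k, 0] = ex + c12 * fx - s12 * fy
                pw[k, 1] = ey + s12 * fx + c12 * fy
        dx = pw[1, 0] - pw[0, 0]
        dy = pw[1, 1] - pw[0, 1]
        L = np.sqrt(dx * dx + dy * dy)
        lengths[m] = L
        ux, uy = dx / L, dy / L
        # d(endpoint)/dq_j = z_hat x (P - joint_center) for points distal to joint j
        for j in range(2):
            d = 0.0
            for k in range(2):
                fr = pframe[m, k]
                sgn = 1.0 if k == 1 else -1.0
                if j == 0 and fr >= 1:
                    rx, ry = pw[k, 0], pw[k, 1]           # about shoulder (origin)
                    d += sgn * (ux * (-ry) + uy * rx)
                elif j == 1 and fr == 2:
                    rx, ry = pw[k, 0] - ex, pw[k, 1] - ey  # about elbow
                    d += sgn * (ux * (-ry) + uy * rx)
            dldq[m, j] = d
    return lengths, dldq


@njit(cache=True)
def muscle_geometry(q1, q2, ml_rest, ml_darm, qrest):
    """Pulley-path muscle lengths and moment arms.

    Muscles wrap the joint capsules, so each keeps a constant moment arm:
    L_m(q) = L_m(q_rest) + sum_j dldq[m, j] * (q_j - q_rest_j), with dldq
    the chord gradients at the rest posture.  Sign-stable over the whole
    workspace (a straight chord would cross the joint centers at extreme
    postures and reverse the muscle's action).
    """
    lengths = np.empty(6)
    for m in range(6):
        lengths[m] = ml_rest[m] + ml_darm[m, 0] * (q1 - qrest[0]) \
            + ml_darm[m, 1] * (q2 - qrest[1])
    return lengths, ml_darm


# ---------------------------------------------------------------------------
# plant dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def plant_rhs(y, drive, ml_rest, ml_darm, qrest, L1, L2, m1, m2, visc,
              kse, kpe, bdm, gain, rest,
              kse_s, kpe_s, b_s, rest_s,
              kse_d, kpe_d, b_d, rest_d,
              g_ib, t0_ib, tau_ib):
    """Time derivative of the 28-dim plant state.  drive = 6 muscle inputs."""
    q1, q2 = y[0], y[1]
    qd = y[2:4]
    dy = np.zeros(NY)

    lengths, dldq = muscle_geometry(q1, q2, ml_rest, ml_darm, qrest)
    xdot = dldq[:, 0] * qd[0] + dldq[:, 1] * qd[1]

    # muscle + intrafusal tensions (Hill-type linear viscoelastic form)
    tau_mus = np.zeros(2)
    for m in range(6):
        T = y[4 + m]
        dx = lengths[m] - rest[m]
        dy[4 + m] = (kse[m] / bdm[m]) * (gain[m] * drive[m] + kpe[m] * dx
                                         + bdm[m] * xdot[m]
                                         - (1.0 + kpe[m] / kse[m]) * T)
        # static bag fiber
        Ts = y[10 + m]
        dxs = lengths[m] - rest_s[m]
        dy[10 + m] = (kse_s[m] / b_s[m]) * (kpe_s[m] * dxs + b_s[m] * xdot[m]
                                            - (1.0 + kpe_s[m] / kse_s[m]) * Ts)
        # dynamic bag fiber
        Td = y[16 + m]
        dxd = lengths[m] - rest_d[m]
        dy[16 + m] = (kse_d[m] / b_d[m]) * (kpe_d[m] * dxd + b_d[m] * xdot[m]
                                            - (1.0 + kpe_d[m] / kse_d[m]) * Td)
        # Golgi tendon organ: rectified-log rate, first-order filter
        Tp = T if T > 0.0 else 0.0
        r = g_ib[m] * np.log(Tp / t0_ib[m] + 1.0)
        dy[22 + m] = (r - y[22 + m]) / tau_ib[m]
        # muscles pull, never push
        Tpull = T if T > 0.0 else 0.0
        tau_mus[0] -= Tpull * dldq[m, 0]
        tau_mus[1] -= Tpull * dldq[m, 1]

    # rigid-body dynamics: compound double pendulum, uniform cylinders, no gravity
    c2 = np.cos(q2)
    s2 = np.sin(q2)
    lc1, lc2 = 0.5 * L1, 0.5 * L2
    I1 = m1 * L1 * L1 / 12.0
    I2 = m2 * L2 * L2 / 12.0
    M11 = m1 * lc1 * lc1 + I1 + m2 * (L1 * L1 + lc2 * lc2 + 2.0 * L1 * lc2 * c2) + I2
    M12 = m2 * (lc2 * lc2 + L1 * lc2 * c2) + I2
    M22 = m2 * lc2 * lc2 + I2
    h = m2 * L1 * lc2 * s2
    # Coriolis/centrifugal + viscous friction
    t1 = tau_mus[0] + h * qd[1] * qd[1] + 2.0 * h * qd[0] * qd[1] - visc * qd[0]
    t2 = tau_mus[1] - h * qd[0] * qd[0] - visc * qd[1]
    det = M11 * M22 - M12 * M12
    dy[0] = qd[0]
    dy[1] = qd[1]
    dy[2] = (M22 * t1 - M12 * t2) / det
    dy[3] = (M11 * t2 - M12 * t1) / det
    return dy


# Dormand-Prince 5(4) coefficients
_DP_C = np.array([0.0, 1/5, 3/10, 4/5, 8/9, 1.0, 1.0])
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1/5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3/40, 9/40, 0.0, 0.0, 0.0, 0.0],
    [44/45, -56/15, 32/9, 0.0, 0.0, 0.0],
    [19372/6561, -25360/2187, 64448/6561, -212/729, 0.0, 0.0],
    [9017/3168, -355/33, 46732/5247, 49/176, -5103/18656, 0.0],
    [35/384, 0.0, 500/1113, 125/192, -2187/6784, 11/84],
])
_DP_B5 = np.array([35/384, 0.0, 500/1113, 125/192, -2187/6784, 11/84, 0.0])
_DP_B4 = np.array([5179/57600, 0.0, 7571/16695, 393/640,
                   -92097/339200, 187/2100, 1/40])


@njit(cache=True)
def plant_advance(y, dt, drive, rtol, atol,
                  ml_rest, ml_darm, qrest, L1, L2, m1, m2, visc,
                  kse, kpe, bdm, gain, rest,
                  kse_s, kpe_s, b_s, rest_s,
                  kse_d, kpe_d, b_d, rest_d,
                  g_ib, t0_ib, tau_ib):
    """Advance the plant by dt with an adaptive Dormand-Prince 5(4) stepper.

    Muscle drives are held constant over the interval.  Returns the new state.
    """
    t = 0.0
    h = dt
    yy = y.copy()
    K = np.empty((7, NY))
    nfail = 0
    while t < dt - 1e-15:
        if h > dt - t:
            h = dt - t
        K[0] = plant_rhs(yy, drive, ml_rest, ml_darm, qrest, L1, L2, m1, m2, visc,
                         kse, kpe, bdm, gain, rest,
                         kse_s, kpe_s, b_s, rest_s,
                         kse_d, kpe_d, b_d, rest_d, g_ib, t0_ib, tau_ib)
        for i in range(1, 7):
            yt = yy.copy()
            for j in range(i):
                a = _DP_A[i, j]
                if a != 0.0:
                    yt += h * a * K[j]
            K[i] = plant_rhs(yt, drive, ml_rest, ml_darm, qrest, L1, L2, m1, m2, visc,
                             kse, kpe, bdm, gain, rest,
                             kse_s, kpe_s, b_s, rest_s,
                             kse_d, kpe_d, b_d, rest_d, g_ib, t0_ib, tau_ib)
        y5 = yy.copy()
        err = 0.0
        for n in range(NY):
            acc5 = 0.0
            acc4 = 0.0
            for i in range(7):
                acc5 += _DP_B5[i] * K[i, n]
                acc4 += _DP_B4[i] * K[i, n]
            ynew = yy[n] + h * acc5
            e = h * (acc5 - acc4)
            sc = atol + rtol * max(abs(yy[n]), abs(ynew))
            err += (e / sc) ** 2
            y5[n] = ynew
        err = np.sqrt(err / NY)
        if err <= 1.0 or h < 1e-7:
            t += h
            yy = y5
        else:
            nfail += 1
        fac = 0.9 * err ** (-0.2) if err > 1e-10 else 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
    return yy


@njit(cache=True)
def afferent_outputs(y, ml_rest, ml_darm, qrest,
                     kse_s, b_s, kse_d, kpe_s,
                     g_ia, f_ia, g_ii, f_ii):
    """(Ia, Ib, II) rates (6 each) from the current plant state.

    Ia and II are linear combinations of intrafusal serial/parallel element
    lengths, read as tension / stiffness; Ib is the GTO filter state.
    """
    q1, q2 = y[0], y[1]
    lengths, dldq = muscle_geometry(q1, q2, ml_rest, ml_darm, qrest)
    xdot = dldq[:, 0] * y[2] + dldq[:, 1] * y[3]
    ia = np.empty(6)
    ib = np.empty(6)
    ii = np.empty(6)
    for m in range(6):
        Ts = y[10 + m]
        Td = y[16 + m]
        ia[m] = g_ia[m] * ((f_ia[m] / kse_s[m]) * Ts
                           + ((1.0 - f_ia[m]) / kse_d[m]) * Td)
        ii[m] = g_ii[m] * ((f_ii[m] / kse_s[m]) * Ts
                           + ((1.0 - f_ii[m]) / kpe_s[m]) * (Ts - b_s[m] * xdot[m]))
        ib[m] = y[22 + m]
        if ia[m] < 0.0:
            ia[m] = 0.0
        if ii[m] < 0.0:
            ii[m] = 0.0
        if ib[m] < 0.0:
            ib[m] = 0.0
    return ia, ib, ii


# ---------------------------------------------------------------------------
# integrated network + plant loop
# ---------------------------------------------------------------------------

# unit kinds / rules (mirrors network.py; numba needs plain ints)
K_CLAMPED, K_SIGMOID, K_NOISY, K_LOG, K_ACT = 0, 1, 2, 3, 4
R_STATIC, R_DH, R_IC, R_CHG, R_GATE = 0, 1, 2, 3, 4


@njit(cache=True)
def _sigm(x, beta, eta):
    return 1.0 / (1.0 + np.exp(-beta * (x - eta)))


@njit(cache=True)
def run_core(steps, dt, do_seed, seed,
             # units
             kind, tau, beta, eta, noise, active,
             a_scale, a_threshold,
             # edges
             esrc, edst, ew, edly, erule, egroup, epa,
             # differential-Hebbian groups
             g_alpha, g_lam, g_wsa, g_wsb, g_lag, g_sign,
             g_pre0, g_pre1, g_post0, g_post1,
             # input correlation
             alpha_ic, ic_wmax, ic_target,
             # CHG synapses
             alpha_chg, tau_chg,
             # ACT unit
             theta_act, tau_act, gamma_act, tau_tilde, reset_rate, chg_gate,
             # adaptation
             adapt_mask, tau_slow, act_trig, adapt_reset, g_adapt,
             # derivative filters
             yf, ym, df, dm, ipa_f, ipa_m, tau_f, tau_m2,
             # dynamic state
             act, buf, dbuf, aff_buf, misc, u_slow, i_adapt, scal,
             # plant coupling
             y, plant_on, freeze_steps, sens_steps, motor_steps, rtol, atol,
             ml_rest, ml_darm, qrest, L1, L2, m1, m2, visc,
             kse, kpe, bdm, gain, rest,
             kse_s, kpe_s, b_s, rest_s,
             kse_d, kpe_d, b_d, rest_d,
             g_ib, t0_ib, tau_ib,
             aff_g_ia, aff_f_ia, aff_g_ii, aff_f_ii,
             # external drive and schedule
             stim, sched_step, sched_sp, sched_tgt,
             # recording
             rec_every, rec_t, rec_act, rec_y, rec_tgt,
             wrec_every, rec_w):
    """Advance the whole model `steps` Euler steps of size dt.

    State arrays (act, buf, ..., y, misc, scal, ew) are updated in place so
    consecutive calls continue seamlessly.  misc = [head, global_step,
    sched_ptr, rec_ptr, wrec_ptr]; scal = [i_tilde].  Returns 0 on success or
    1 + unit index if a non-finite activity appeared.
    """
    if do_seed != 0:
        np.random.seed(seed)
    n = act.shape[0]
    E = esrc.shape[0]
    H = buf.shape[1]
    nG = g_alpha.shape[0]
    head = misc[0]
    gstep = misc[1]
    sptr = misc[2]
    rptr = misc[3]
    wptr = misc[4]
    sqdt = np.sqrt(dt)
    dscale = 1.0 / (tau_m2 - tau_f)

    I = np.zeros(n)
    ipa = np.zeros(n)
    d1 = np.zeros(n)
    d2 = np.zeros(n)
    out_sum = np.zeros(n)
    in_sum = np.zeros(n)
    ic_sum = np.zeros(n)
    drive = np.zeros(6)
    gm1 = np.zeros(nG)
    gm2 = np.zeros(nG)

    for s in range(steps):
        # -- schedule: clamp SP sources ---------------------------------
        while sptr + 1 < sched_step.shape[0] and sched_step[sptr + 1] <= gstep:
            sptr += 1
        if sched_step.shape[0] > 0 and sched_step[sptr] <= gstep:
            for i in range(6):
                if active[i] != 0:
                    act[i] = sched_sp[sptr, i]
                    buf[i, head] = act[i]

        # -- input sums --------------------------------------------------
        for u in range(n):
            I[u] = stim[u]
            ipa[u] = 0.0
        gate_in = 0.0
        for e in range(E):
            v = ew[e] * buf[esrc[e], (head - edly[e]) % H]
            if erule[e] == R_GATE:
                gate_in += v
            else:
                I[edst[e]] += v
            if epa[e] != 0:
                ipa[edst[e]] += v
        for k in range(18):
            u = 36 + k
            I[u] += a_scale[k] * aff_buf[k, (head - sens_steps) % H]
        for u in range(n):
            if adapt_mask[u] != 0:
                I[u] -= g_adapt * i_adapt[u]

        # -- derivative estimates (exponential-smoother cascade) ----------
        for u in range(n):
            yf[u] += dt * (act[u] - yf[u]) / tau_f
            ym[u] += dt * (act[u] - ym[u]) / tau_m2
            d1[u] = (yf[u] - ym[u]) * dscale
            df[u] += dt * (d1[u] - df[u]) / tau_f
            dm[u] += dt * (d1[u] - dm[u]) / tau_m2
            d2[u] = (df[u] - dm[u]) * dscale

        # -- plasticity ----------------------------------------------------
        if nG > 0:
            for u in range(n):
                out_sum[u] = 0.0
                in_sum[u] = 0.0
            for e in range(E):
                if erule[e] == R_DH:
                    out_sum[esrc[e]] += ew[e]
                    in_sum[edst[e]] += ew[e]
            for g in range(nG):
                m2s = 0.0
                for u in range(g_pre0[g], g_pre1[g]):
                    m2s += d2[u]
                gm2[g] = m2s / (g_pre1[g] - g_pre0[g])
                m1s = 0.0
                for u in range(g_post0[g], g_post1[g]):
                    m1s += dbuf[u, (head - g_lag[g]) % H]
                gm1[g] = m1s / (g_post1[g] - g_post0[g])
            for e in range(E):
                if erule[e] == R_DH:
                    g = egroup[e]
                    delta = -g_sign[g] * (d2[esrc[e]] - gm2[g]) \
                        * (dbuf[edst[e], (head - g_lag[g]) % H] - gm1[g])
                    zsa = g_wsa[g] / out_sum[esrc[e]] if out_sum[esrc[e]] > 1e-12 else 1.0
                    zsb = g_wsb[g] / in_sum[edst[e]] if in_sum[edst[e]] > 1e-12 else 1.0
                    # normalization sign chosen so sums relax toward targets
                    w = ew[e] + dt * (g_alpha[g] * ew[e]
                                      * (delta + g_lam[g] * (0.5 * (zsa + zsb) - 1.0)))
                    ew[e] = w if w > 0.0 else 0.0
        if alpha_ic > 0.0:
            for u in range(n):
                if ic_target[u] > 0.0:
                    ipa_f[u] += dt * (ipa[u] - ipa_f[u]) / tau_f
                    ipa_m[u] += dt * (ipa[u] - ipa_m[u]) / tau_m2
            for u in range(n):
                ic_sum[u] = 0.0
            for e in range(E):
                if erule[e] == R_IC:
                    d = edst[e]
                    dipa = (ipa_f[d] - ipa_m[d]) * dscale
                    pre = buf[esrc[e], (head - edly[e]) % H]
                    w = ew[e] + dt * alpha_ic * ew[e] * pre * dipa
                    ew[e] = w if w > 0.0 else 0.0
                    ic_sum[d] += ew[e]
            for e in range(E):
                if erule[e] == R_IC:
                    d = edst[e]
                    if ic_sum[d] > 1e-12:
                        w = ew[e] * ic_target[d] / ic_sum[d]
                        ew[e] = w if w < ic_wmax else ic_wmax
        for e in range(E):
            if erule[e] == R_CHG:
                ew[e] += dt * (alpha_chg * abs(d1[esrc[e]]) - ew[e]) / tau_chg

        # -- unit updates --------------------------------------------------
        for u in range(n):
            if active[u] == 0 or kind[u] == K_CLAMPED:
                continue
            if kind[u] == K_SIGMOID:
                act[u] += dt * (_sigm(I[u], beta[u], eta[u]) - act[u]) / tau[u]
            elif kind[u] == K_NOISY:
                act[u] += dt * (_sigm(I[u], beta[u], eta[u]) - act[u]) / tau[u] \
                    + noise[u] * sqdt * np.random.normal()
                if act[u] < 0.0:
                    act[u] = 0.0
                elif act[u] > 1.0:
                    act[u] = 1.0
            elif kind[u] == K_LOG:
                k = u - 36
                arg = 1.0 + I[u] - a_threshold[k]
                f = np.log(arg) if arg > 1.0 else 0.0
                act[u] += dt * (f - act[u]) / tau[u]
            elif kind[u] == K_ACT:
                sI = _sigm(I[u], beta[u], eta[u])
                if gate_in > chg_gate:
                    da = -reset_rate * act[u]
                elif sI < theta_act:
                    da = act[u] * (sI - theta_act)
                else:
                    sdot = sI - _sigm(scal[0], beta[u], eta[u])
                    da = (sI - theta_act) * (1.0 - act[u] + gamma_act * sdot) / tau_act
                act[u] += dt * da
                scal[0] += dt * (I[u] - scal[0]) / tau_tilde
                if act[u] < 0.0:
                    act[u] = 0.0

        # -- adaptation slow variables ------------------------------------
        for u in range(n):
            if adapt_mask[u] != 0:
                u_slow[u] += dt * (act[u] - u_slow[u]) / tau_slow
                if act[72] > act_trig and i_adapt[u] < adapt_reset:
                    i_adapt[u] = u_slow[u] * u_slow[u]
                else:
                    i_adapt[u] -= dt * i_adapt[u] / tau_slow

        # -- push history --------------------------------------------------
        head = (head + 1) % H
        for u in range(n):
            buf[u, head] = act[u]
            dbuf[u, head] = d1[u]

        # -- plant ---------------------------------------------------------
        if plant_on != 0 and gstep >= freeze_steps:
            for mu in range(6):
                drive[mu] = buf[66 + mu, (head - motor_steps) % H]
            y[:] = plant_advance(y, dt, drive, rtol, atol,
                                 ml_rest, ml_darm, qrest, L1, L2, m1, m2, visc,
                                 kse, kpe, bdm, gain, rest,
                                 kse_s, kpe_s, b_s, rest_s,
                                 kse_d, kpe_d, b_d, rest_d,
                                 g_ib, t0_ib, tau_ib)
        ia, ib, ii = afferent_outputs(y, ml_rest, ml_darm, qrest,
                                      kse_s, b_s, kse_d, kpe_s,
                                      aff_g_ia, aff_f_ia, aff_g_ii, aff_f_ii)
        for mu in range(6):
            aff_buf[mu, head] = ia[mu]
            aff_buf[6 + mu, head] = ib[mu]
            aff_buf[12 + mu, head] = ii[mu]

        gstep += 1

        # -- recording -----------------------------------------------------
        if rec_every > 0 and gstep % rec_every == 0 and rptr < rec_t.shape[0]:
            rec_t[rptr] = gstep * dt
            for u in range(n):
                rec_act[rptr, u] = act[u]
            for j in range(NY):
                rec_y[rptr, j] = y[j]
            rec_tgt[rptr, 0] = sched_tgt[sptr, 0] if sched_step.shape[0] > 0 else 0.0
            rec_tgt[rptr, 1] = sched_tgt[sptr, 1] if sched_step.shape[0] > 0 else 0.0
            rptr += 1
        if wrec_every > 0 and gstep % wrec_every == 0 and wptr < rec_w.shape[0]:
            for e in range(E):
                rec_w[wptr, e] = ew[e]
            wptr += 1

        # -- sanity --------------------------------------------------------
        if gstep % 200 == 0:
            for u in range(n):
                if not np.isfinite(act[u]):
                    misc[0] = head; misc[1] = gstep
                    misc[2] = sptr; misc[3] = rptr; misc[4] = wptr
                    return 1 + u

    misc[0] = head
    misc[1] = gstep
    misc[2] = sptr
    misc[3] = rptr
    misc[4] = wptr
    return 0
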