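"""Compiled integration kernel for the powered simplest walker.

Everything in this module is numba-jitted and operates on plain float64
scalars/arrays.  The public package surface lives in :mod:`gaitscape.dynamics`
and :mod:`gaitscape.control`; nothing here validates its inputs.

The swing phase is integrated with an adaptive Dormand-Prince 5(4) scheme.
Events (foot-ground contact, hip-spring switch at phi = 0, fall guards) are
located by sampling each accepted step for sign changes, bisecting a cubic
Hermite interpolant, and then polishing the event time with Newton iterations
that re-integrate tiny sub-steps, so event states are resolved to the same
accuracy as the integration tolerance.
"""

import numpy as np
from numba import njit

# step outcome codes
COMPLETED = 0
FELL = 1
NO_CONTACT = 2
STEP_FAIL = 3

# rollout outcome codes (control layer)
CONVERGED = 0
NOT_CONVERGED = 1
ROLLOUT_FELL = 2
ROLLOUT_FAIL = 3

_HALF_PI = np.pi / 2.0

# Dormand-Prince 5(4) tableau (same coefficients as scipy's RK45)
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
_E1, _E3, _E4, _E5, _E6, _E7 = (71.0 / 57600.0, -71.0 / 16695.0,
                                71.0 / 1920.0, -17253.0 / 339200.0,
                                22.0 / 525.0, -1.0 / 40.0)


@njit(cache=True)
def _rhs(y, k, out):
    th, thd, ph, phd = y[0], y[1], y[2], y[3]
    thdd = np.sin(th)
    out[0] = thd
    out[1] = thdd
    out[2] = phd
    out[3] = thdd + thd * thd * np.sin(ph) - np.cos(th) * np.sin(ph) - k * ph


@njit(cache=True)
def _rk_step(y, f, h, k, ynew, fnew, work):
    """One DP5(4) step; returns the scaled error norm (accept if <= 1)."""
    k2 = work[0]
    k3 = work[1]
    k4 = work[2]
    k5 = work[3]
    k6 = work[4]
    ytmp = work[5]
    for i in range(4):
        ytmp[i] = y[i] + h * _A21 * f[i]
    _rhs(ytmp, k, k2)
    for i in range(4):
        ytmp[i] = y[i] + h * (_A31 * f[i] + _A32 * k2[i])
    _rhs(ytmp, k, k3)
    for i in range(4):
        ytmp[i] = y[i] + h * (_A41 * f[i] + _A42 * k2[i] + _A43 * k3[i])
    _rhs(ytmp, k, k4)
    for i in range(4):
        ytmp[i] = y[i] + h * (_A51 * f[i] + _A52 * k2[i] + _A53 * k3[i]
                              + _A54 * k4[i])
    _rhs(ytmp, k, k5)
    for i in range(4):
        ytmp[i] = y[i] + h * (_A61 * f[i] + _A62 * k2[i] + _A63 * k3[i]
                              + _A64 * k4[i] + _A65 * k5[i])
    _rhs(ytmp, k, k6)
    for i in range(4):
        ynew[i] = y[i] + h * (_B1 * f[i] + _B3 * k3[i] + _B4 * k4[i]
                              + _B5 * k5[i] + _B6 * k6[i])
    _rhs(ynew, k, fnew)
    err = 0.0
    for i in range(4):
        ei = h * (_E1 * f[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                  + _E6 * k6[i] + _E7 * fnew[i])
        ay = abs(y[i])
        ayn = abs(ynew[i])
        scale = 1.0 if ay < ayn else 0.0
        scale = (ayn if scale == 1.0 else ay)
        den = 1.0 + scale  # atol = rtol = tol, factored out by caller
        e = ei / den
        err += e * e
    return np.sqrt(err / 4.0)


@njit(cache=True)
def _event_val(code, y):
    if code == 0:                      # foot-ground contact surface
        return y[2] - 2.0 * y[0]
    elif code == 1:                    # hip-spring switch
        return y[2]
    elif code == 2:                    # stance rate reversal (rock-back)
        return y[1]
    elif code == 3:                    # forward fall guard
        return y[0] - _HALF_PI
    else:                              # backward fall guard
        return y[0] + _HALF_PI


@njit(cache=True)
def _event_rate(code, f):
    if code == 0:
        return f[2] - 2.0 * f[0]
    elif code == 1:
        return f[2]
    elif code == 2:
        return f[1]
    else:
        return f[0]


@njit(cache=True)
def _hermite(y0, f0, y1, f1, h, s, out):
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    for i in range(4):
        out[i] = h00 * y0[i] + h10 * h * f0[i] + h01 * y1[i] + h11 * h * f1[i]


@njit(cache=True)
def _locate_event(code, y0, f0, y1, f1, h, s_min, tmp):
    """Earliest root of event `code` on the Hermite interpolant in (s_min, 1].

    Returns the normalized root position, or 2.0 when there is no sign
    change.  A zero value at the left edge is not treated as a crossing (the
    contact function is exactly zero at step start by construction).
    """
    ns = 8
    s_prev = s_min
    _hermite(y0, f0, y1, f1, h, s_prev, tmp)
    g_prev = _event_val(code, tmp)
    for j in range(1, ns + 1):
        s_cur = s_min + (1.0 - s_min) * j / ns
        _hermite(y0, f0, y1, f1, h, s_cur, tmp)
        g_cur = _event_val(code, tmp)
        crossed = False
        if g_prev != 0.0:
            if g_prev * g_cur < 0.0 or g_cur == 0.0:
                crossed = True
        if crossed:
            a, b = s_prev, s_cur
            ga = g_prev
            for _ in range(60):
                m = 0.5 * (a + b)
                _hermite(y0, f0, y1, f1, h, m, tmp)
                gm = _event_val(code, tmp)
                if ga * gm <= 0.0:
                    b = m
                else:
                    a = m
                    ga = gm
            return 0.5 * (a + b)
        s_prev = s_cur
        g_prev = g_cur
    return 2.0


@njit(cache=True)
def _advance_to(t0, y0, f0, dt, k, work, yout, fout):
    """Integrate exactly dt forward with a single DP5 step (dt is tiny)."""
    _rk_step(y0, f0, dt, k, yout, fout, work)
    return t0 + dt


@njit(cache=True)
def _polish_event(code, t0, y0, f0, s, h, k, work, y_e, f_e):
    """Land exactly on the event: one partial step then Newton on time."""
    t_e = _advance_to(t0, y0, f0, s * h, k, work, y_e, f_e)
    yt = np.empty(4)
    ft = np.empty(4)
    for _ in range(12):
        g = _event_val(code, y_e)
        if abs(g) < 1e-14:
            break
        gdot = _event_rate(code, f_e)
        if gdot == 0.0:
            break
        dt = -g / gdot
        if dt > 0.5 * h:
            dt = 0.5 * h
        elif dt < -0.5 * h:
            dt = -0.5 * h
        t_e = _advance_to(t_e, y_e, f_e, dt, k, work, yt, ft)
        for i in range(4):
            y_e[i] = yt[i]
            f_e[i] = ft[i]
    return t_e


@njit(cache=True)
def swing_foot_height(th, ph):
    return np.cos(th) - np.cos(th - ph)


@njit(cache=True)
def _foot_height_rate(y):
    th, thd, ph, phd = y[0], y[1], y[2], y[3]
    return -np.sin(th) * thd + np.sin(th - ph) * (thd - phd)


@njit(cache=True)
def integrate_swing(y0, k1, k2, tol, t_max, guard, traj, rec):
    """Integrate the swing phase until an accepted foot-ground contact.

    Parameters are dimensionless.  `traj` is a pre-allocated (n, 6) buffer
    filled with (t, theta, theta_dot, phi, phi_dot, k_active) rows when
    `rec` is true.

    Returns (status, t_contact, y_pre, n_recorded, n_switch) where
    n_switch counts hip-spring switch events (phi zero crossings): the
    physical gait family has exactly one per step, splitting the swing
    into a +phi half on k1 and a -phi half on k2.
    """
    y = y0.copy()
    nrec = 0
    n_switch = 0
    if abs(y[0]) >= _HALF_PI:
        return FELL, 0.0, y, nrec, n_switch
    k_active = k1 if y[2] > 0.0 else k2
    f = np.empty(4)
    _rhs(y, k_active, f)
    ynew = np.empty(4)
    fnew = np.empty(4)
    y_e = np.empty(4)
    f_e = np.empty(4)
    tmp = np.empty(4)
    work = np.empty((6, 4))
    t = 0.0
    h = 0.01
    h_max = 0.25
    # events are masked for a tiny window after they fire, per event code:
    # at a periodic gait the contact surface and the spring switch cross
    # zero simultaneously at mid-stance, so one shared guard would mask the
    # genuine switch behind a rejected contact candidate
    t_guards = np.full(5, -1.0)
    cap = traj.shape[0]
    if rec and nrec < cap:
        traj[nrec, 0] = t
        for i in range(4):
            traj[nrec, 1 + i] = y[i]
        traj[nrec, 5] = k_active
        nrec += 1
    while t < t_max:
        if h < 1e-13:
            return STEP_FAIL, t, y, nrec, n_switch
        if h > h_max:
            h = h_max
        err = _rk_step(y, f, h, k_active, ynew, fnew, work) / tol
        if err > 1.0:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            h *= fac
            continue
        # accepted step on [t, t + h]: look for the earliest event
        best_s = 2.0
        best_code = -1
        for code in range(5):
            s_min = 0.0
            if t_guards[code] > t:
                s_min = (t_guards[code] - t) / h
                if s_min > 1.0:
                    s_min = 1.0
            s = _locate_event(code, y, f, ynew, fnew, h, s_min, tmp)
            if s < best_s:
                best_s = s
                best_code = code
        if best_code < 0:
            t += h
            for i in range(4):
                y[i] = ynew[i]
                f[i] = fnew[i]
            if rec and nrec < cap:
                traj[nrec, 0] = t
                for i in range(4):
                    traj[nrec, 1 + i] = y[i]
                traj[nrec, 5] = k_active
                nrec += 1
            if err == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * err ** -0.2
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h *= fac
            continue
        t_e = _polish_event(best_code, t, y, f, best_s, h, k_active,
                            work, y_e, f_e)
        if best_code == 0:
            # candidate contact: require the swing foot ahead of the scuff
            # configuration (phi < -guard) and descending
            if y_e[2] < -guard and _foot_height_rate(y_e) < 0.0:
                if rec and nrec < cap:
                    traj[nrec, 0] = t_e
                    for i in range(4):
                        traj[nrec, 1 + i] = y_e[i]
                    traj[nrec, 5] = k_active
                    nrec += 1
                return COMPLETED, t_e, y_e, nrec, n_switch
        elif best_code == 1:
            # hip-spring switch: active stiffness follows the sign of phi
            k_active = k2 if y_e[3] < 0.0 else k1
            n_switch += 1
        elif best_code == 2:
            # stance rate hits zero before mid-stance: rocks backward
            if y_e[0] > 1e-3:
                return FELL, t_e, y_e, nrec, n_switch
        else:
            return FELL, t_e, y_e, nrec, n_switch
        # resume just past the event
        t_guards[best_code] = t_e + 1e-9
        t = t_e
        for i in range(4):
            y[i] = y_e[i]
        _rhs(y, k_active, f)
        if rec and nrec < cap:
            traj[nrec, 0] = t
            for i in range(4):
                traj[nrec, 1 + i] = y[i]
            traj[nrec, 5] = k_active
            nrec += 1
    return NO_CONTACT, t, y, nrec, n_switch


@njit(cache=True)
def heelstrike(y_pre, P, out):
    """Composite push-off + inelastic heel-strike transition."""
    th = y_pre[0]
    thd = y_pre[1]
    c2 = np.cos(2.0 * th)
    s2 = np.sin(2.0 * th)
    thd_post = c2 * thd + s2 * P
    out[0] = -th
    out[1] = thd_post
    out[2] = -2.0 * th
    out[3] = (1.0 - c2) * thd_post


@njit(cache=True)
def step_reduced(theta, theta_dot, P, k1, k2, tol, t_max, guard):
    """Full step-to-step return map on the reduced state (theta, theta_dot).

    The start state is expanded through the transition structure
    (phi = 2 theta, phi_dot = (1 - cos 2 theta) theta_dot), the swing phase
    is integrated to contact, and the push-off + heel-strike transition with
    impulse P is applied.

    Returns (status, theta_next, theta_dot_next, SL, SF, step_time,
    n_switch).
    """
    y0 = np.empty(4)
    y0[0] = theta
    y0[1] = theta_dot
    y0[2] = 2.0 * theta
    y0[3] = (1.0 - np.cos(2.0 * theta)) * theta_dot
    no_traj = np.empty((1, 6))
    status, t_c, y_pre, _, n_sw = integrate_swing(y0, k1, k2, tol, t_max,
                                                  guard, no_traj, False)
    if status != COMPLETED:
        return status, 0.0, 0.0, 0.0, 0.0, 0.0, n_sw
    post = np.empty(4)
    heelstrike(y_pre, P, post)
    sl = 2.0 * abs(np.sin(y_pre[0]))
    sf = 1.0 / t_c
    return COMPLETED, post[0], post[1], sl, sf, t_c, n_sw


@njit(cache=True)
def rollout(theta, theta_dot, n_steps,
            K, xn_th, xn_thd, P_n, k1_n, k2_n, use_feedback,
            xs_th, xs_thd, conv_tol, early_tol, allow_early,
            tol, t_max, guard, sl_out, sf_out, th_out, thd_out):
    """Walk up to n_steps from a reduced start state.

    With `use_feedback` the once-per-step law u = u_n - K (x - x_n) is
    applied each step (push-off clamped at zero); otherwise the nominal
    actuations are held constant.  Convergence is measured against
    (xs_th, xs_thd).  When `allow_early`, the walk is declared converged as
    soon as the state error drops below `early_tol` (the map is
    deterministic, so from there the remaining steps repeat the target
    cycle).

    Per-step realized step length / frequency / start state are written into
    the provided buffers.  Returns (outcome, steps_taken, final_error).
    """
    th = theta
    thd = theta_dot
    err = max(abs(th - xs_th), abs(thd - xs_thd))
    for i in range(n_steps):
        if use_feedback:
            dth = th - xn_th
            dthd = thd - xn_thd
            P = P_n - (K[0, 0] * dth + K[0, 1] * dthd)
            k1 = k1_n - (K[1, 0] * dth + K[1, 1] * dthd)
            k2 = k2_n - (K[2, 0] * dth + K[2, 1] * dthd)
            if P < 0.0:
                P = 0.0
        else:
            P = P_n
            k1 = k1_n
            k2 = k2_n
        status, th2, thd2, sl, sf, st, _ = step_reduced(
            th, thd, P, k1, k2, tol, t_max, guard)
        if status != COMPLETED:
            if status == STEP_FAIL:
                return ROLLOUT_FAIL, i, err
            return ROLLOUT_FELL, i, err
        th = th2
        thd = thd2
        sl_out[i] = sl
        sf_out[i] = sf
        th_out[i] = th
        thd_out[i] = thd
        err = max(abs(th - xs_th), abs(thd - xs_thd))
        if allow_early and err < early_tol:
            return CONVERGED, i + 1, err
    if err < conv_tol:
        return CONVERGED, n_steps, err
    return NOT_CONVERGED, n_steps, err
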