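"""Independent reference implementations used only to cross-check tests.

The swing-phase oracle integrates the same equations with scipy's DOP853
and scipy's own event machinery, sharing no code with the package's
compiled integrator.
"""

import numpy as np
from scipy.integrate import solve_ivp

HALF_PI = np.pi / 2.0


def rhs(t, y, k):
    th, thd, ph, phd = y
    thdd = np.sin(th)
    return [thd, thdd,
            phd, thdd + thd * thd * np.sin(ph) - np.cos(th) * np.sin(ph)
            - k * ph]


def foot_height_rate(y):
    th, thd, ph, phd = y
    return -np.sin(th) * thd + np.sin(th - ph) * (thd - phd)


def integrate_swing_scipy(y0, k1, k2, t_end=None, tol=1e-12, t_max=50.0,
                          guard=1e-6):
    """Piecewise DOP853 integration of the swing phase.

    With ``t_end`` the state at that exact time is returned (spring
    switches handled, contacts ignored).  Otherwise integration runs until
    an accepted foot-ground contact (phi < -guard, descending foot) and
    returns (t_contact, y_pre).
    """
    y = np.asarray(y0, float).copy()
    t = 0.0
    horizon = t_end if t_end is not None else t_max

    def ev_switch(t, y, k):
        return y[2]
    ev_switch.terminal = True

    def ev_contact(t, y, k):
        return y[2] - 2.0 * y[0]
    ev_contact.terminal = True

    while t < horizon - 1e-12:
        k = k1 if y[2] > 0.0 else k2
        # nudge past any event zero sitting exactly at the start point
        pre = solve_ivp(rhs, (t, t + 1e-7), y, args=(k,), method="DOP853",
                        rtol=tol, atol=tol)
        t, y = pre.t[-1], pre.y[:, -1]
        events = [ev_switch] if t_end is not None else [ev_switch,
                                                        ev_contact]
        sol = solve_ivp(rhs, (t, horizon), y, args=(k,), method="DOP853",
                        rtol=tol, atol=tol, events=events, max_step=0.25)
        if sol.status == 1:          # an event fired
            fired = [(te[0], i) for i, te in enumerate(sol.t_events)
                     if len(te)]
            te, idx = min(fired)
            ye = sol.y_events[idx][0]
            if t_end is None and idx == 1:
                if ye[2] < -guard and foot_height_rate(ye) < 0.0:
                    return te, ye
            t, y = te, ye
        else:
            t, y = sol.t[-1], sol.y[:, -1]
    if t_end is not None:
        return t, y
    raise RuntimeError("no accepted contact before t_max")


def heelstrike_matrix(theta):
    """Eq-style 4x4 transition matrix and push-off vector (direct form)."""
    c2 = np.cos(2.0 * theta)
    s2 = np.sin(2.0 * theta)
    M = np.array([[-1.0, 0.0, 0.0, 0.0],
                  [0.0, c2, 0.0, 0.0],
                  [-2.0, 0.0, 0.0, 0.0],
                  [0.0, c2 * (1.0 - c2), 0.0, 0.0]])
    v = np.array([0.0, s2, 0.0, s2 * (1.0 - c2)])
    return M, v
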