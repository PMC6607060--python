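"""Compiled adaptive time integration for the 7-ODE cell model.

Embedded Dormand-Prince RK5(4) with PI-free step control, specialised to the
cell model right-hand side.  The stimulus is piecewise constant over
segments whose boundaries are forced step boundaries (square pulses break
smoothness, so steps never straddle an on/off edge).  Solution values on a
uniform output grid are produced by cubic Hermite interpolation from the
accepted steps, which matches the O(h^4) local accuracy needed at the
default tolerances.

The explicit pair is adequate here: the fastest time scale is tau_m
(0.12 ms nominal), so the adaptive step stays well inside the stability
region without the cost of an implicit solver.  A safety cap on the total
number of steps turns pathological parameter sets into an explicit error
status instead of a hang.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import _rhs

__all__ = ["integrate_segments", "integrate_to_crossing", "STATUS_OK",
           "STATUS_STEP_FAIL", "STATUS_NONFINITE"]

STATUS_OK = 0
STATUS_STEP_FAIL = 1      # step count exceeded
STATUS_NONFINITE = 2      # NaN/Inf encountered

_MAX_STEPS = 4_000_000

# Dormand-Prince 5(4) Butcher tableau
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
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
# 4th-order solution weights (for the error estimate), b - bhat
_E1, _E3, _E4, _E5, _E6, _E7 = (71.0 / 57600.0, -71.0 / 16695.0,
                                71.0 / 1920.0, -17253.0 / 339200.0,
                                22.0 / 525.0, -1.0 / 40.0)


@njit(cache=True)
def _dp_step(y, p, istim, h, f0, k2, k3, k4, k5, k6, f_new, y_new, y_tmp):
    """One Dormand-Prince step of size h from y with derivative f0.

    Fills y_new and f_new (FSAL) and returns the scaled error estimate
    numerator array implicitly via y_tmp.  Returns the raw error vector in
    y_tmp on exit.
    """
    n = y.shape[0]
    for i in range(n):
        y_tmp[i] = y[i] + h * _A21 * f0[i]
    _rhs(y_tmp, p, istim, k2)
    for i in range(n):
        y_tmp[i] = y[i] + h * (_A31 * f0[i] + _A32 * k2[i])
    _rhs(y_tmp, p, istim, k3)
    for i in range(n):
        y_tmp[i] = y[i] + h * (_A41 * f0[i] + _A42 * k2[i] + _A43 * k3[i])
    _rhs(y_tmp, p, istim, k4)
    for i in range(n):
        y_tmp[i] = y[i] + h * (_A51 * f0[i] + _A52 * k2[i] + _A53 * k3[i]
                               + _A54 * k4[i])
    _rhs(y_tmp, p, istim, k5)
    for i in range(n):
        y_tmp[i] = y[i] + h * (_A61 * f0[i] + _A62 * k2[i] + _A63 * k3[i]
                               + _A64 * k4[i] + _A65 * k5[i])
    _rhs(y_tmp, p, istim, k6)
    for i in range(n):
        y_new[i] = y[i] + h * (_B1 * f0[i] + _B3 * k3[i] + _B4 * k4[i]
                               + _B5 * k5[i] + _B6 * k6[i])
    _rhs(y_new, p, istim, f_new)
    for i in range(n):
        y_tmp[i] = h * (_E1 * f0[i] + _E3 * k3[i] + _E4 * k4[i]
                        + _E5 * k5[i] + _E6 * k6[i] + _E7 * f_new[i])


@njit(cache=True)
def _hermite(t, t0, t1, y0, y1, f0, f1, out):
    """Cubic Hermite interpolation of the state at t in [t0, t1]."""
    h = t1 - t0
    s = (t - t0) / h
    h00 = (1.0 + 2.0 * s) * (1.0 - s) * (1.0 - s)
    h10 = s * (1.0 - s) * (1.0 - s)
    h01 = s * s * (3.0 - 2.0 * s)
    h11 = s * s * (s - 1.0)
    for i in range(y0.shape[0]):
        out[i] = (h00 * y0[i] + h10 * h * f0[i]
                  + h01 * y1[i] + h11 * h * f1[i])


@njit(cache=True)
def integrate_segments(p, y0, seg_times, seg_amps, t_out, rtol, atol,
                       max_step):
    """Integrate over stimulus segments, sampling the state on t_out.

    Parameters
    ----------
    p : (36,) parameter array.
    y0 : (7,) initial state at seg_times[0].
    seg_times : (n_seg+1,) strictly increasing segment boundaries, ms.
    seg_amps : (n_seg,) stimulus current in each segment, uA/cm^2.
    t_out : uniform, increasing output grid within [seg_times[0], seg_times[-1]].
    rtol, atol, max_step : solver controls.

    Returns
    -------
    (Y, y_end, status): Y is (len(t_out), 7) interpolated states, y_end the
    final state, status a STATUS_* code.
    """
    n = y0.shape[0]
    n_out = t_out.shape[0]
    Y = np.empty((n_out, n))
    y = y0.copy()
    f0 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    f_new = np.empty(n)
    y_new = np.empty(n)
    err = np.empty(n)
    y_interp = np.empty(n)

    i_out = 0
    # emit any output points at/before the start time
    while i_out < n_out and t_out[i_out] <= seg_times[0]:
        for i in range(n):
            Y[i_out, i] = y[i]
        i_out += 1

    n_steps = 0
    for iseg in range(seg_amps.shape[0]):
        t = seg_times[iseg]
        t_end = seg_times[iseg + 1]
        istim = seg_amps[iseg]
        _rhs(y, p, istim, f0)
        h = min(max_step, t_end - t)
        if h <= 0.0:
            continue
        # shrink the very first trial step near sharp stimulus edges
        if istim != 0.0 and h > 0.01:
            h = 0.01
        while t < t_end:
            if n_steps > _MAX_STEPS:
                return Y, y, STATUS_STEP_FAIL
            if t + h > t_end:
                h = t_end - t
            _dp_step(y, p, istim, h, f0, k2, k3, k4, k5, k6, f_new, y_new,
                     err)
            # scaled RMS error norm
            e = 0.0
            for i in range(n):
                sc = atol + rtol * max(abs(y[i]), abs(y_new[i]))
                r = err[i] / sc
                e += r * r
            e = np.sqrt(e / n)
            n_steps += 1
            if not np.isfinite(e):
                # wild trial step (e.g. tau_h underflow at extreme V):
                # reject and retry with a much smaller step
                h = h * 0.1
                if h < 1e-12:
                    return Y, y, STATUS_NONFINITE
                continue
            if e <= 1.0:
                t_new = t + h
                # fill output points inside (t, t_new]
                while i_out < n_out and t_out[i_out] <= t_new:
                    _hermite(t_out[i_out], t, t_new, y, y_new, f0, f_new,
                             y_interp)
                    for i in range(n):
                        Y[i_out, i] = y_interp[i]
                    i_out += 1
                t = t_new
                for i in range(n):
                    y[i] = y_new[i]
                    f0[i] = f_new[i]
                # step-size growth
                if e == 0.0:
                    fac = 5.0
                else:
                    fac = min(5.0, 0.9 * e ** (-0.2))
                h = min(max_step, h * fac)
            else:
                h = h * max(0.2, 0.9 * e ** (-0.2))
            if h < 1e-12:
                return Y, y, STATUS_NONFINITE
    # flush trailing points (numerical round-off at the end time)
    while i_out < n_out:
        for i in range(n):
            Y[i_out, i] = y[i]
        i_out += 1
    return Y, y, STATUS_OK


@njit(cache=True)
def integrate_to_crossing(p, y0, seg_times, seg_amps, v_cross, rtol, atol,
                          max_step):
    """Integrate until V first exceeds v_cross; early exit.

    Returns (crossed, t_cross, status).  t_cross is the time of the first
    accepted step end with V > v_cross (an upper bound on the true crossing
    time, adequate for threshold bisection).
    """
    n = y0.shape[0]
    y = y0.copy()
    f0 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    f_new = np.empty(n)
    y_new = np.empty(n)
    err = np.empty(n)

    if y[0] > v_cross:
        return True, seg_times[0], STATUS_OK

    n_steps = 0
    for iseg in range(seg_amps.shape[0]):
        t = seg_times[iseg]
        t_end = seg_times[iseg + 1]
        istim = seg_amps[iseg]
        _rhs(y, p, istim, f0)
        h = min(max_step, t_end - t)
        if h <= 0.0:
            continue
        if istim != 0.0 and h > 0.01:
            h = 0.01
        while t < t_end:
            if n_steps > _MAX_STEPS:
                return False, t, STATUS_STEP_FAIL
            if t + h > t_end:
                h = t_end - t
            _dp_step(y, p, istim, h, f0, k2, k3, k4, k5, k6, f_new, y_new,
                     err)
            e = 0.0
            for i in range(n):
                sc = atol + rtol * max(abs(y[i]), abs(y_new[i]))
                r = err[i] / sc
                e += r * r
            e = np.sqrt(e / n)
            n_steps += 1
            if not np.isfinite(e):
                h = h * 0.1
                if h < 1e-12:
                    return False, t, STATUS_NONFINITE
                continue
            if e <= 1.0:
                t = t + h
                for i in range(n):
                    y[i] = y_new[i]
                    f0[i] = f_new[i]
                if y[0] > v_cross:
                    return True, t, STATUS_OK
                if e == 0.0:
                    fac = 5.0
                else:
                    fac = min(5.0, 0.9 * e ** (-0.2))
                h = min(max_step, h * fac)
            else:
                h = h * max(0.2, 0.9 * e ** (-0.2))
            if h < 1e-12:
                return False, t, STATUS_NONFINITE
    return False, seg_times[-1], STATUS_OK
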