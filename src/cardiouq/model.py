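"""Gating functions, ionic currents and right-hand side of the cell model.

Six Hodgkin-Huxley currents (I_Na, I_K1, I_to, I_CaL, I_Kr, I_Ks) over seven
state variables (V, m, h, s, f, xr, xs).  Gates z, r, d and y equilibrate
instantaneously and are evaluated as algebraic functions of V inside the
current expressions; they are never integrated.

Steady states are sigmoids Y_inf(V) = 1 / (1 + exp(-+(V - E_Y)/k_Y)) (minus
sign for activation gates, plus for inactivation).  All time constants are
voltage-independent except tau_h, which is h-shaped:

    tau_h(V) = 2 tau_h0 exp(delta_h (V - Eh)/kh) / (1 + exp((V - Eh)/kh))

The compiled kernels operate on the raw 36-entry parameter array in
canonical order (see :mod:`cardiouq.parameters`); the public functions wrap
them for :class:`ParameterSet` inputs.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numba import njit

from .parameters import (
    CM,
    GATE_EK_NAMES,
    GATES,
    ParameterSet,
)

__all__ = [
    "gate_steady_state",
    "tau_h",
    "ionic_currents",
    "rhs",
    "initial_conditions",
    "CURRENT_NAMES",
]

CURRENT_NAMES: tuple[str, ...] = ("INa", "IK1", "Ito", "ICaL", "IKr", "IKs")

# Parameter-array indices (canonical order; kept in sync with PARAM_NAMES).
(I_GNA, I_EM, I_KM, I_TAUM, I_EH, I_KH, I_DH, I_TAUH0,
 I_GK1, I_EZ, I_KZ,
 I_GTO, I_ER, I_KR, I_ES, I_KS, I_TAUS,
 I_GCAL, I_ED, I_KD, I_EF, I_KF, I_TAUF,
 I_GKR, I_EXR, I_KXR, I_TAUXR, I_EY, I_KY,
 I_GKS, I_EXS, I_KXS, I_TAUXS,
 I_ENA, I_EK, I_ECA) = range(36)


@njit(cache=True, fastmath=False, error_model="numpy")
def _sig_act(V, E, k):
    # activation sigmoid, increasing in V
    return 1.0 / (1.0 + np.exp(-(V - E) / k))


@njit(cache=True, fastmath=False, error_model="numpy")
def _sig_inact(V, E, k):
    # inactivation sigmoid, decreasing in V
    return 1.0 / (1.0 + np.exp((V - E) / k))


@njit(cache=True, fastmath=False, error_model="numpy")
def _tau_h(V, p):
    # 2 tau_h0 e^{delta_h x} / (1 + e^x), x = (V - Eh)/kh, evaluated stably
    x = (V - p[I_EH]) / p[I_KH]
    d = p[I_DH]
    if x > 0.0:
        return 2.0 * p[I_TAUH0] * np.exp((d - 1.0) * x) / (1.0 + np.exp(-x))
    return 2.0 * p[I_TAUH0] * np.exp(d * x) / (1.0 + np.exp(x))


@njit(cache=True, fastmath=False, error_model="numpy")
def _currents(V, m, h, s, f, xr, xs, p, out):
    # out[0..5] = INa, IK1, Ito, ICaL, IKr, IKs  (uA/cm^2)
    out[0] = p[I_GNA] * m * m * m * h * h * (V - p[I_ENA])
    out[1] = p[I_GK1] * _sig_inact(V, p[I_EZ], p[I_KZ]) * (V - p[I_EK])
    out[2] = p[I_GTO] * _sig_act(V, p[I_ER], p[I_KR]) * s * (V - p[I_EK])
    out[3] = p[I_GCAL] * _sig_act(V, p[I_ED], p[I_KD]) * f * (V - p[I_ECA])
    out[4] = p[I_GKR] * xr * _sig_inact(V, p[I_EY], p[I_KY]) * (V - p[I_EK])
    out[5] = p[I_GKS] * xs * (V - p[I_EK])


@njit(cache=True, fastmath=False, error_model="numpy")
def _i_ion_total(V, m, h, s, f, xr, xs, p):
    total = p[I_GNA] * m * m * m * h * h * (V - p[I_ENA])
    total += p[I_GK1] * _sig_inact(V, p[I_EZ], p[I_KZ]) * (V - p[I_EK])
    total += p[I_GTO] * _sig_act(V, p[I_ER], p[I_KR]) * s * (V - p[I_EK])
    total += p[I_GCAL] * _sig_act(V, p[I_ED], p[I_KD]) * f * (V - p[I_ECA])
    total += p[I_GKR] * xr * _sig_inact(V, p[I_EY], p[I_KY]) * (V - p[I_EK])
    total += p[I_GKS] * xs * (V - p[I_EK])
    return total


@njit(cache=True, fastmath=False, error_model="numpy")
def _rhs(y, p, istim, dy):
    """dy/dt for state y = (V, m, h, s, f, xr, xs) with stimulus istim."""
    V = y[0]
    m, h, s, f, xr, xs = y[1], y[2], y[3], y[4], y[5], y[6]
    dy[0] = (istim - _i_ion_total(V, m, h, s, f, xr, xs, p)) / 1.0  # Cm = 1
    dy[1] = (_sig_act(V, p[I_EM], p[I_KM]) - m) / p[I_TAUM]
    dy[2] = (_sig_inact(V, p[I_EH], p[I_KH]) - h) / _tau_h(V, p)
    dy[3] = (_sig_inact(V, p[I_ES], p[I_KS]) - s) / p[I_TAUS]
    dy[4] = (_sig_inact(V, p[I_EF], p[I_KF]) - f) / p[I_TAUF]
    dy[5] = (_sig_act(V, p[I_EXR], p[I_KXR]) - xr) / p[I_TAUXR]
    dy[6] = (_sig_act(V, p[I_EXS], p[I_KXS]) - xs) / p[I_TAUXS]


@njit(cache=True, fastmath=False, error_model="numpy")
def _steady_gates(V, p, out):
    """Steady-state values of the six state-variable gates at voltage V."""
    out[0] = _sig_act(V, p[I_EM], p[I_KM])     # m
    out[1] = _sig_inact(V, p[I_EH], p[I_KH])   # h
    out[2] = _sig_inact(V, p[I_ES], p[I_KS])   # s
    out[3] = _sig_inact(V, p[I_EF], p[I_KF])   # f
    out[4] = _sig_act(V, p[I_EXR], p[I_KXR])   # xr
    out[5] = _sig_act(V, p[I_EXS], p[I_KXS])   # xs


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def gate_steady_state(V, gate: str, params: ParameterSet):
    """Steady-state occupancy Y_inf(V) of a named gate.

    Parameters
    ----------
    V : float or ndarray
        Transmembrane voltage, mV.
    gate : str
        One of m, h, z, r, s, d, f, xr, y, xs.
    params : ParameterSet

    Returns
    -------
    float or ndarray in (0, 1), increasing in V for activation gates and
    decreasing for inactivation gates.
    """
    if gate not in GATES:
        raise KeyError(f"unknown gate {gate!r}; expected one of {sorted(GATES)}")
    E_name, k_name = GATE_EK_NAMES[gate]
    E, k = params[E_name], params[k_name]
    V = np.asarray(V, dtype=float)
    sign = -1.0 if GATES[gate].kind == "activation" else 1.0
    arg = np.clip(sign * (V - E) / k, -700.0, 700.0)  # avoid exp overflow
    out = 1.0 / (1.0 + np.exp(arg))
    return float(out) if out.ndim == 0 else out


def tau_h(V, params: ParameterSet):
    """Voltage-dependent time constant of the h gate, ms (h-shaped)."""
    V = np.asarray(V, dtype=float)
    x = (V - params.Eh) / params.kh
    d = params.delta_h
    # numerically stable split at x = 0
    out = np.where(
        x > 0,
        2.0 * params.tau_h0 * np.exp((d - 1.0) * np.minimum(x, 700.0)) / (1.0 + np.exp(-np.abs(x))),
        2.0 * params.tau_h0 * np.exp(d * np.maximum(x, -700.0)) / (1.0 + np.exp(-np.abs(x))),
    )
    return float(out) if out.ndim == 0 else out


def ionic_currents(state, params: ParameterSet) -> dict[str, float]:
    """The six ionic currents at a given state, uA/cm^2.

    `state` is (V, m, h, s, f, xr, xs).  Instantaneous gates (z, r, d, y)
    are evaluated at the supplied V.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (7,):
        raise ValueError("state must have 7 entries (V, m, h, s, f, xr, xs)")
    out = np.empty(6)
    _currents(y[0], y[1], y[2], y[3], y[4], y[5], y[6], params.values, out)
    return dict(zip(CURRENT_NAMES, out.tolist()))


def rhs(t: float, state, params: ParameterSet,
        stim: Callable[[float], float] | float = 0.0) -> np.ndarray:
    """Time derivative of the 7-entry state vector.

    dV/dt = (I_stim - sum I_ion)/Cm; positive stimulus depolarizes.
    dY/dt = (Y_inf(V) - Y)/tau_Y for the six state-variable gates.

    `stim` may be a constant (uA/cm^2) or a callable of t.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (7,):
        raise ValueError("state must have 7 entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state vector")
    istim = float(stim(t)) if callable(stim) else float(stim)
    dy = np.empty(7)
    _rhs(y, params.values, istim, dy)
    return dy


def initial_conditions(params: ParameterSet) -> np.ndarray:
    """Resting initial state: V = EK, gates at their steady state at EK."""
    y0 = np.empty(7)
    y0[0] = params.EK
    _steady_gates(params.EK, params.values, y0[1:])
    return y0


@njit(cache=True, fastmath=False, error_model="numpy")
def _dvdt_grid(states, p, istim, out):
    dy = np.empty(7)
    for i in range(states.shape[0]):
        _rhs(states[i], p, istim[i], dy)
        out[i] = dy[0]


def dvdt_on_grid(states: np.ndarray, params: ParameterSet,
                 istim: np.ndarray) -> np.ndarray:
    """dV/dt evaluated from the model right-hand side on an output grid.

    Avoids finite-difference grid artifacts in upstroke-velocity features.
    `states` is (n, 7), `istim` the stimulus current at each grid time.
    """
    states = np.ascontiguousarray(states, dtype=np.float64)
    istim = np.ascontiguousarray(istim, dtype=np.float64)
    out = np.empty(states.shape[0])
    _dvdt_grid(states, params.values, istim, out)
    return out
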