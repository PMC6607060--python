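"""Stimulus protocols and time integration of the cell model.

A square-wave stimulus (default 0.5 ms) initiates the action potential.
Protocols: a single stimulus, bisection for the threshold stimulus, 1 Hz
(or arbitrary-BCL) pacing with state carry-over, and the dynamic APD
restitution protocol.

Solver defaults: adaptive step, rtol 1e-6 / atol 1e-8, max step 1 ms,
forced step boundaries at stimulus on/off edges.  Output is sampled on a
uniform grid (default dt_out = 0.05 ms); dV/dt for feature extraction is
evaluated from the model right-hand side on that grid rather than by finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _integrate
from .model import CURRENT_NAMES, _currents, dvdt_on_grid
from .parameters import ParameterSet, STATE_NAMES

__all__ = [
    "StimulusProtocol",
    "APTrace",
    "SolverError",
    "ThresholdError",
    "SolverSettings",
    "simulate_ap",
    "find_threshold",
    "pace",
    "dynamic_restitution",
]

#: Voltage (mV) that must be exceeded within DEPOL_WINDOW ms of stimulus
#: onset for a response to count as a depolarization.
DEPOL_VOLTAGE = 0.0
DEPOL_WINDOW = 50.0


class SolverError(RuntimeError):
    """Integration failure; carries the offending parameter set."""

    def __init__(self, message: str, params: ParameterSet):
        super().__init__(f"{message} (params: {params!r})")
        self.params = params


class ThresholdError(RuntimeError):
    """Threshold bracketing failure; carries the offending parameter set."""

    def __init__(self, message: str, params: ParameterSet):
        super().__init__(f"{message} (params: {params!r})")
        self.params = params


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 1.0  # ms


DEFAULT_SOLVER = SolverSettings()


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-wave stimulus: a pulse of `amplitude` uA/cm^2 for `duration`
    ms starting at `onset`; optionally repeated every `period` ms for
    `n_beats` beats."""

    amplitude: float
    onset: float = 0.0
    duration: float = 0.5
    period: float | None = None
    n_beats: int | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be non-negative")
        if self.onset < 0:
            raise ValueError("stimulus onset must be non-negative")
        if self.period is not None and self.period <= self.duration:
            raise ValueError("pacing period must exceed stimulus duration")

    def current(self, t):
        """Stimulus current at time t (vectorized)."""
        t = np.asarray(t, dtype=float)
        if self.period is None:
            phase = t - self.onset
        else:
            phase = np.mod(t - self.onset, self.period)
        on = (phase >= 0) & (phase < self.duration)
        out = np.where(on, self.amplitude, 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class APTrace:
    """A uniformly sampled voltage time course from one simulation.

    `states` holds all seven state variables on the grid; per-current traces
    and model-evaluated dV/dt are computed on demand.
    """

    t: np.ndarray
    states: np.ndarray
    params: ParameterSet
    stim: StimulusProtocol
    dt_out: float
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.t.size, 7):
            raise ValueError("states must be (len(t), 7)")
        dt = np.diff(self.t)
        if self.t.size > 1 and not (np.all(dt > 0)
                                    and np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("t must be strictly increasing and uniform")

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def state_at(self, t: float) -> np.ndarray:
        """State at grid time nearest t."""
        i = int(np.argmin(np.abs(self.t - t)))
        return self.states[i]

    def currents(self) -> dict[str, np.ndarray]:
        """Per-current traces (uA/cm^2) on the output grid."""
        n = self.t.size
        out = np.empty((n, 6))
        p = self.params.values
        buf = np.empty(6)
        for i in range(n):
            V, m, h, s, f, xr, xs = self.states[i]
            _currents(V, m, h, s, f, xr, xs, p, buf)
            out[i] = buf
        return {name: out[:, j].copy() for j, name in enumerate(CURRENT_NAMES)}

    def dvdt(self) -> np.ndarray:
        """dV/dt on the grid, evaluated from the model right-hand side."""
        istim = np.asarray(self.stim.current(self.t), dtype=float)
        return dvdt_on_grid(self.states, self.params, istim)

    def to_frame(self, include_currents: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t})
        for j, name in enumerate(STATE_NAMES):
            df[name] = self.states[:, j]
        if include_currents:
            for name, series in self.currents().items():
                df[name] = series
        return df


def _stim_segments(stim: StimulusProtocol, t0: float, t1: float):
    """Piecewise-constant stimulus segments covering [t0, t1]."""
    edges = [t0]
    amps = []
    if stim.period is None:
        pulses = [(stim.onset, stim.onset + stim.duration)]
    else:
        pulses = []
        k = 0
        n_max = stim.n_beats if stim.n_beats is not None else int(1e9)
        while k < n_max:
            on = stim.onset + k * stim.period
            if on >= t1:
                break
            pulses.append((on, on + stim.duration))
            k += 1
    for on, off in pulses:
        on = max(t0, min(on, t1))
        off = max(t0, min(off, t1))
        if off <= on:
            continue
        if on > edges[-1]:
            amps.append(0.0)
            edges.append(on)
        amps.append(stim.amplitude)
        edges.append(off)
    if edges[-1] < t1:
        amps.append(0.0)
        edges.append(t1)
    return np.asarray(edges), np.asarray(amps)


def _integrate_trace(params: ParameterSet, y0: np.ndarray,
                     stim: StimulusProtocol, t0: float, t1: float,
                     dt_out: float, solver: SolverSettings):
    seg_t, seg_a = _stim_segments(stim, t0, t1)
    n_out = int(round((t1 - t0) / dt_out)) + 1
    t_out = t0 + dt_out * np.arange(n_out)
    Y, y_end, status = _integrate.integrate_segments(
        params.values, y0, seg_t, seg_a, t_out,
        solver.rtol, solver.atol, solver.max_step)
    if status != _integrate.STATUS_OK:
        raise SolverError(
            f"ODE integration failed with status {status}", params)
    if not np.all(np.isfinite(Y)):
        raise SolverError("non-finite values in solution", params)
    return t_out, Y, y_end


def simulate_ap(params: ParameterSet, stim: StimulusProtocol,
                duration: float = 1000.0, dt_out: float = 0.05,
                y0: np.ndarray | None = None,
                solver: SolverSettings = DEFAULT_SOLVER) -> APTrace:
    """Simulate one action potential under a single square-pulse stimulus.

    Starts from the resting initial conditions (V = EK, gates at steady
    state) unless `y0` is given.  Returns the trace on a uniform `dt_out`
    grid over [0, duration].
    """
    from .model import initial_conditions

    if duration < stim.onset + stim.duration:
        raise ValueError("duration must cover the stimulus pulse")
    if y0 is None:
        y0 = initial_conditions(params)
    t_out, Y, _ = _integrate_trace(params, np.asarray(y0, dtype=float),
                                   stim, 0.0, duration, dt_out, solver)
    return APTrace(t=t_out, states=Y, params=params, stim=stim,
                   dt_out=dt_out, solver=solver)


def _depolarizes(params: ParameterSet, amplitude: float,
                 stim_duration: float, solver: SolverSettings) -> bool:
    """Does a pulse of this amplitude drive V above 0 mV within 50 ms?"""
    from .model import initial_conditions

    y0 = initial_conditions(params)
    seg_t = np.array([0.0, stim_duration, DEPOL_WINDOW])
    seg_a = np.array([amplitude, 0.0])
    crossed, _, status = _integrate.integrate_to_crossing(
        params.values, y0, seg_t, seg_a, DEPOL_VOLTAGE,
        solver.rtol, solver.atol, solver.max_step)
    if status != _integrate.STATUS_OK:
        raise SolverError("integration failed during threshold search",
                          params)
    return bool(crossed)


def find_threshold(params: ParameterSet, search_hi: float = 200.0,
                   search_lo: float = 0.0, rel_tol: float = 0.005,
                   stim_duration: float = 0.5,
                   solver: SolverSettings = DEFAULT_SOLVER) -> float:
    """Minimum 0.5 ms square-pulse amplitude that elicits depolarization.

    Depolarization means V exceeds 0 mV within 50 ms of stimulus onset.
    Bisection on [search_lo, search_hi] to a relative tolerance `rel_tol`;
    the returned amplitude depolarizes, and the lower bisection endpoint
    (within rel_tol below it) does not.
    """
    if search_hi <= search_lo:
        raise ValueError("search_hi must exceed search_lo")
    if not _depolarizes(params, search_hi, stim_duration, solver):
        raise ThresholdError(
            f"no depolarization even at amplitude {search_hi}", params)
    lo, hi = search_lo, search_hi
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _depolarizes(params, mid, stim_duration, solver):
            hi = mid
        else:
            lo = mid
    return hi


def pace(params: ParameterSet, bcl: float = 1000.0, n_beats: int = 10,
         amplitude: float | None = None, stim_duration: float = 0.5,
         dt_out: float = 0.05,
         solver: SolverSettings = DEFAULT_SOLVER) -> list[APTrace]:
    """Pace at basic cycle length `bcl` for `n_beats`, carrying state over.

    Stimulus amplitude defaults to 1.1x the parameter set's threshold.
    Returns one APTrace per beat, each aligned to its own stimulus (t = 0 at
    the beat's stimulus onset).
    """
    from .model import initial_conditions

    if bcl < 100.0:
        raise ValueError("bcl must be at least 100 ms")
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    if amplitude is None:
        amplitude = 1.1 * find_threshold(params, stim_duration=stim_duration,
                                         solver=solver)
    stim = StimulusProtocol(amplitude=amplitude, onset=0.0,
                            duration=stim_duration)
    y = initial_conditions(params)
    beats: list[APTrace] = []
    for _ in range(n_beats):
        t_out, Y, y_end = _integrate_trace(params, y, stim, 0.0, bcl,
                                           dt_out, solver)
        beats.append(APTrace(t=t_out, states=Y, params=params, stim=stim,
                             dt_out=dt_out, solver=solver))
        y = y_end
    return beats


def dynamic_restitution(params: ParameterSet,
                        bcl_list: Sequence[float],
                        beats_per_bcl: int = 20,
                        amplitude: float | None = None,
                        dt_out: float = 0.05,
                        solver: SolverSettings = DEFAULT_SOLVER
                        ) -> pd.DataFrame:
    """Dynamic APD95 restitution: pace down a decreasing BCL schedule.

    At each BCL the model is paced for `beats_per_bcl` beats (state carried
    continuously through the whole protocol) and APD95 of the final beat is
    extracted.  DI = BCL - APD95.  Rows that lose 1:1 capture are flagged
    (captured = False) rather than fatal.

    Returns a DataFrame with columns BCL, APD95, DI, captured.
    """
    from .features import apd95 as _apd95
    from .model import initial_conditions

    bcls = list(bcl_list)
    if any(b2 >= b1 for b1, b2 in zip(bcls, bcls[1:])):
        raise ValueError("bcl_list must be strictly decreasing")
    if beats_per_bcl < 1:
        raise ValueError("beats_per_bcl must be positive")
    if amplitude is None:
        amplitude = 1.1 * find_threshold(params, solver=solver)

    y = initial_conditions(params)
    rows = []
    for bcl in bcls:
        stim = StimulusProtocol(amplitude=amplitude, onset=0.0, duration=0.5)
        trace = None
        for _ in range(beats_per_bcl):
            t_out, Y, y_end = _integrate_trace(params, y, stim, 0.0, bcl,
                                               dt_out, solver)
            trace = APTrace(t=t_out, states=Y, params=params, stim=stim,
                            dt_out=dt_out, solver=solver)
            y = y_end
        apd = _apd95(trace)
        captured = apd is not None and np.max(trace.V) > DEPOL_VOLTAGE
        rows.append({
            "BCL": float(bcl),
            "APD95": float(apd) if apd is not None else np.nan,
            "DI": float(bcl - apd) if apd is not None else np.nan,
            "captured": bool(captured),
        })
    return pd.DataFrame(rows)
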