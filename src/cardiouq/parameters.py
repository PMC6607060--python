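"""Parameterization of the canine epicardial action potential model.

The model has a 36-entry parameter vector: six maximal conductances, ten
half-(in)activation voltages, ten sigmoid slope factors, five constant time
constants, the tau_h scale and asymmetry factor, and the three Nernst
potentials.  The Nernst potentials (ENa, EK, ECa) are environmental
parameters: they are part of the vector but are never perturbed when
sampling.  The specific membrane capacitance Cm = 1 uF/cm^2 is a fixed model
constant, not a vector entry.

Units: conductances mS/uF, voltages mV, time constants ms, delta_h
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "SAMPLED_NAMES",
    "FIXED_NAMES",
    "NORMAL_NAMES",
    "LOGNORMAL_NAMES",
    "NOMINAL",
    "CM",
    "N_PARAMS",
    "N_SAMPLED",
    "GateSpec",
    "GATES",
    "STATE_NAMES",
    "ParameterSet",
    "nominal_parameters",
]

# Fixed 36-column order used everywhere (sample matrices, CSV round-trips).
PARAM_NAMES: tuple[str, ...] = (
    # I_Na
    "gNa", "Em", "km", "tau_m", "Eh", "kh", "delta_h", "tau_h0",
    # I_K1
    "gK1", "Ez", "kz",
    # I_to
    "gto", "Er", "kr", "Es", "ks", "tau_s",
    # I_CaL
    "gCaL", "Ed", "kd", "Ef", "kf", "tau_f",
    # I_Kr
    "gKr", "Exr", "kxr", "tau_xr", "Ey", "ky",
    # I_Ks
    "gKs", "Exs", "kxs", "tau_xs",
    # Nernst potentials (environmental, never sampled)
    "ENa", "EK", "ECa",
)

N_PARAMS = len(PARAM_NAMES)  # 36

#: Nominal parameter values, by name.
NOMINAL: dict[str, float] = {
    "gNa": 12.0,
    "Em": -52.244,
    "km": 6.5472,
    "tau_m": 0.12,
    "Eh": -78.7,
    "kh": 5.93,
    "delta_h": 0.799163,
    "tau_h0": 6.80738,
    "gK1": 0.73893,
    "Ez": -91.9655,
    "kz": 12.4997,
    "gto": 0.1688,
    "Er": 14.3116,
    "kr": 11.462,
    "Es": -47.9286,
    "ks": 4.9314,
    "tau_s": 9.90669,
    "gCaL": 0.11503,
    "Ed": 0.7,
    "kd": 4.3,
    "Ef": -15.7,
    "kf": 4.6,
    "tau_f": 30.0,
    "gKr": 0.056,
    "Exr": -26.6,
    "kxr": 6.5,
    "tau_xr": 334.0,
    "Ey": -49.6,
    "ky": 23.5,
    "gKs": 0.0080,
    "Exs": 24.6,
    "kxs": 12.1,
    "tau_xs": 628.0,
    "ENa": 65.0,
    "EK": -85.0,
    "ECa": 50.0,
}

#: Specific membrane capacitance, uF/cm^2 (fixed).
CM: float = 1.0

FIXED_NAMES: tuple[str, ...] = ("ENa", "EK", "ECa")
SAMPLED_NAMES: tuple[str, ...] = tuple(n for n in PARAM_NAMES if n not in FIXED_NAMES)
N_SAMPLED = len(SAMPLED_NAMES)  # 33 free entries of the 36-entry vector

#: Half-(in)activation voltages: normally distributed under uncertainty.
NORMAL_NAMES: tuple[str, ...] = (
    "Em", "Eh", "Ez", "Er", "Es", "Ed", "Ef", "Exr", "Ey", "Exs",
)
#: Positive parameters (g, k, tau, delta_h): lognormally distributed.
LOGNORMAL_NAMES: tuple[str, ...] = tuple(
    n for n in SAMPLED_NAMES if n not in NORMAL_NAMES
)

# Parameters that must be strictly positive.
_POSITIVE_NAMES = frozenset(LOGNORMAL_NAMES)

STATE_NAMES: tuple[str, ...] = ("V", "m", "h", "s", "f", "xr", "xs")


@dataclass(frozen=True)
class GateSpec:
    """Classification of one gating variable.

    kind: 'activation' (steady state increases with V) or 'inactivation'.
    dynamic: 'state-variable' gates obey tau_Y dY/dt = Y_inf - Y;
        'instantaneous' gates are algebraic functions of V.
    tau_kind: 'constant', 'h-shaped' (voltage-dependent tau_h), or 'none'
        for instantaneous gates.
    """

    name: str
    kind: str
    dynamic: str
    tau_kind: str


GATES: dict[str, GateSpec] = {
    "m": GateSpec("m", "activation", "state-variable", "constant"),
    "h": GateSpec("h", "inactivation", "state-variable", "h-shaped"),
    "z": GateSpec("z", "inactivation", "instantaneous", "none"),
    "r": GateSpec("r", "activation", "instantaneous", "none"),
    "s": GateSpec("s", "inactivation", "state-variable", "constant"),
    "d": GateSpec("d", "activation", "instantaneous", "none"),
    "f": GateSpec("f", "inactivation", "state-variable", "constant"),
    "xr": GateSpec("xr", "activation", "state-variable", "constant"),
    "y": GateSpec("y", "inactivation", "instantaneous", "none"),
    "xs": GateSpec("xs", "activation", "state-variable", "constant"),
}

#: (E, k) parameter names for each gate's steady-state sigmoid.
GATE_EK_NAMES: dict[str, tuple[str, str]] = {
    "m": ("Em", "km"),
    "h": ("Eh", "kh"),
    "z": ("Ez", "kz"),
    "r": ("Er", "kr"),
    "s": ("Es", "ks"),
    "d": ("Ed", "kd"),
    "f": ("Ef", "kf"),
    "xr": ("Exr", "kxr"),
    "y": ("Ey", "ky"),
    "xs": ("Exs", "kxs"),
}


class ParameterSet:
    """Immutable 36-entry parameter vector with attribute access by name.

    Backed by a float64 array in the canonical :data:`PARAM_NAMES` order, so
    it can be passed directly to the compiled model kernels.
    """

    __slots__ = ("_values",)

    _index = {name: i for i, name in enumerate(PARAM_NAMES)}

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=np.float64).copy()
        if arr.shape != (N_PARAMS,):
            raise ValueError(
                f"expected {N_PARAMS} parameter values, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("parameter values must be finite")
        for name in _POSITIVE_NAMES:
            if arr[self._index[name]] <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive")
        arr.setflags(write=False)
        object.__setattr__(self, "_values", arr)

    # -- constructors -----------------------------------------------------
    @classmethod
    def nominal(cls, **overrides: float) -> "ParameterSet":
        """The Table-of-nominal-values parameter set, optionally overridden."""
        d = dict(NOMINAL)
        unknown = set(overrides) - set(d)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        d.update(overrides)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise KeyError(f"missing parameter names: {sorted(missing)}")
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return cls([mapping[n] for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterSet":
        return cls(arr)

    # -- access -----------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return float(self._values[self._index[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return float(self._values[self._index[name]])

    @property
    def values(self) -> np.ndarray:
        """Read-only float64 array in canonical order."""
        return self._values

    @property
    def Cm(self) -> float:
        return CM

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self._values)}

    def replace(self, **overrides: float) -> "ParameterSet":
        d = self.to_dict()
        unknown = set(overrides) - set(d)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        d.update(overrides)
        return ParameterSet.from_dict(d)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return bool(np.array_equal(self._values, other._values))

    def __hash__(self) -> int:
        return hash(self._values.tobytes())

    def __repr__(self) -> str:
        diffs = {
            n: float(v)
            for n, v in zip(PARAM_NAMES, self._values)
            if v != NOMINAL[n]
        }
        if not diffs:
            return "ParameterSet.nominal()"
        inner = ", ".join(f"{k}={v:g}" for k, v in diffs.items())
        return f"ParameterSet.nominal({inner})"


def nominal_parameters(**overrides: float) -> ParameterSet:
    """Convenience alias for :meth:`ParameterSet.nominal`."""
    return ParameterSet.nominal(**overrides)
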