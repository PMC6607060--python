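"""Scalar quantities of interest and AP behavior classification.

QOIs extracted from a single AP trace:

* MaxUpstrokeVelocity (mV/ms) and its time (ms from stimulus onset),
  evaluated from the model right-hand side on the output grid;
* APA (mV): maximum voltage during the upstroke minus the resting potential
  (voltage at stimulus onset);
* APD (ms): time from activation (first upward crossing of -70 mV, linearly
  interpolated) to the first subsequent downward crossing of -70 mV;
* NotchMin / NotchMax (mV): the local minimum during the AP notch and the
  local maximum ending it, when the spike-and-dome morphology is present.

A fixed -70 mV APD threshold (rather than APD90) decouples APD from APA.
Undefined QOIs are flagged explicitly, never reported as zero.

Behavior taxonomy for 1000 ms traces, from counting interior local extrema
(0.5 mV prominence filter to suppress solver wiggle):

1. dome without spike -- one local maximum later than 10 ms, no local
   minimum (voltage keeps rising after the upstroke);
2. spike without dome -- one local maximum within 10 ms, no local minimum
   (monotone decay after the peak);
3. oscillatory -- more than one local minimum (EADs, repolarization
   failure, low-voltage oscillations), or the late-rising special case
   with two maxima and one minimum whose first maximum is later than
   10 ms;
4. normal -- anything else, including the nominal spike-and-dome AP.

Behavior 3 splits by the voltage at t = 1000 ms: back at rest (< -75 mV,
3A, EADs en route), repolarization failure (> -25 mV, 3B), or low-voltage
oscillations in between (3C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .protocols import APTrace

__all__ = [
    "QOIRecord",
    "BehaviorLabel",
    "extract_qois",
    "apd95",
    "classify_behavior",
    "classify_oscillatory_subtype",
    "QOI_NAMES",
    "APD_THRESHOLD",
    "PROMINENCE",
]

#: Fixed repolarization threshold for APD, mV.
APD_THRESHOLD = -70.0
#: Prominence filter for local-extrema counting, mV.
PROMINENCE = 0.5
#: Upstroke search window after stimulus onset, ms.
UPSTROKE_WINDOW = 50.0
#: Spike-vs-dome time boundary for the behavior taxonomy, ms.
SPIKE_TIME_LIMIT = 10.0

QOI_NAMES = (
    "threshold",
    "max_upstroke_velocity",
    "time_of_max_upstroke_velocity",
    "apa",
    "apd",
    "notch_min",
    "notch_max",
)


@dataclass(frozen=True)
class QOIRecord:
    """Scalar features of one AP; None marks an undefined quantity."""

    threshold: Optional[float] = None            # uA/cm^2 (protocol-level)
    max_upstroke_velocity: Optional[float] = None  # mV/ms
    time_of_max_upstroke_velocity: Optional[float] = None  # ms from onset
    apa: Optional[float] = None                  # mV
    apd: Optional[float] = None                  # ms
    notch_min: Optional[float] = None            # mV
    notch_max: Optional[float] = None            # mV

    def __post_init__(self):
        if self.apa is not None and self.apa <= 0:
            raise ValueError("apa must be positive when defined")
        if self.apd is not None and self.apd <= 0:
            raise ValueError("apd must be positive when defined")
        if (self.notch_min is not None and self.notch_max is not None
                and self.notch_min > self.notch_max):
            raise ValueError("notch_min must not exceed notch_max")

    def defined(self, name: str) -> bool:
        return getattr(self, name) is not None

    def as_dict(self) -> dict[str, float]:
        """Flat dict with NaN for undefined values plus *_defined flags."""
        out: dict[str, float] = {}
        for name in QOI_NAMES:
            v = getattr(self, name)
            out[name] = float(v) if v is not None else float("nan")
            out[f"{name}_defined"] = v is not None
        return out


@dataclass(frozen=True)
class BehaviorLabel:
    """Categorical AP behavior: major class 1-4, sub-class for class 3."""

    major: int
    sub: Optional[str] = None

    def __post_init__(self):
        if self.major not in (1, 2, 3, 4):
            raise ValueError("major must be 1, 2, 3 or 4")
        if self.sub is not None and self.major != 3:
            raise ValueError("sub-behavior only applies to major class 3")
        if self.sub is not None and self.sub not in ("3A", "3B", "3C"):
            raise ValueError("sub must be 3A, 3B or 3C")

    def __str__(self) -> str:
        return self.sub if self.sub is not None else str(self.major)


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _first_upward_crossing(t, V, level, start_idx=0):
    for i in range(max(start_idx, 1), t.size):
        if V[i - 1] < level <= V[i]:
            return _interp_crossing(t[i - 1], t[i], V[i - 1], V[i], level), i
    return None, None


def _first_downward_crossing(t, V, level, start_idx):
    for i in range(max(start_idx, 1), t.size):
        if V[i - 1] >= level > V[i]:
            return _interp_crossing(t[i - 1], t[i], V[i - 1], V[i], level), i
    return None, None


def _extrema(trace: APTrace):
    """Interior local maxima/minima of the post-stimulus trace.

    Returns (t_max, v_max, t_min, v_min) with times measured from stimulus
    onset; extrema below the prominence filter are discarded.
    """
    t0 = trace.stim.onset + trace.stim.duration
    mask = trace.t > t0
    t = trace.t[mask]
    V = trace.V[mask]
    imax, _ = find_peaks(V, prominence=PROMINENCE)
    imin, _ = find_peaks(-V, prominence=PROMINENCE)
    onset = trace.stim.onset
    return (t[imax] - onset, V[imax], t[imin] - onset, V[imin])


def extract_qois(trace: APTrace, threshold: Optional[float] = None
                 ) -> QOIRecord:
    """Extract the scalar QOIs from one AP trace.

    `threshold` is the protocol-level threshold stimulus, passed through.
    If the trace never depolarizes (V stays at or below 0 mV within 50 ms
    of onset), the upstroke and APD fields are flagged undefined.
    """
    onset = trace.stim.onset
    t = trace.t
    V = trace.V
    i_onset = int(np.searchsorted(t, onset))
    v_rest = V[i_onset]

    # upstroke window: onset to the voltage maximum within 50 ms
    win = (t >= onset) & (t <= onset + UPSTROKE_WINDOW)
    idx_win = np.nonzero(win)[0]
    i_peak = idx_win[np.argmax(V[idx_win])]
    depolarized = V[i_peak] > 0.0

    muv = t_muv = apa = apd = None
    if depolarized:
        dvdt = trace.dvdt()
        up = idx_win[idx_win <= i_peak]
        j = up[np.argmax(dvdt[up])]
        muv = float(dvdt[j])
        t_muv = float(t[j] - onset)
        apa = float(V[i_peak] - v_rest)

        t_act, i_act = _first_upward_crossing(t, V, APD_THRESHOLD, i_onset)
        if t_act is not None:
            t_rep, _ = _first_downward_crossing(t, V, APD_THRESHOLD, i_act)
            if t_rep is not None:
                apd = float(t_rep - t_act)

    # notch: after the first post-stimulus local max (the spike), a local
    # min followed by a local max
    notch_min = notch_max = None
    if depolarized:
        t_max, v_max, t_min, v_min = _extrema(trace)
        if t_max.size >= 1 and t_min.size >= 1:
            t_spike = t_max[0]
            after = t_min > t_spike
            if np.any(after):
                k = int(np.argmax(after))  # first min after the spike
                later_max = t_max > t_min[k]
                if np.any(later_max):
                    m = int(np.argmax(later_max))
                    notch_min = float(v_min[k])
                    notch_max = float(v_max[m])

    return QOIRecord(
        threshold=threshold,
        max_upstroke_velocity=muv,
        time_of_max_upstroke_velocity=t_muv,
        apa=apa,
        apd=apd,
        notch_min=notch_min,
        notch_max=notch_max,
    )


def apd95(trace: APTrace) -> Optional[float]:
    """APD95: time from activation to 95% repolarization of the amplitude.

    Activation is the first upward -70 mV crossing; the repolarization
    level is Vmax - 0.95 * (Vmax - V_rest) with V_rest the voltage at
    stimulus onset.  Returns None if undefined.
    """
    onset = trace.stim.onset
    t, V = trace.t, trace.V
    i_onset = int(np.searchsorted(t, onset))
    v_rest = V[i_onset]
    t_act, i_act = _first_upward_crossing(t, V, APD_THRESHOLD, i_onset)
    if t_act is None:
        return None
    i_peak = i_act + int(np.argmax(V[i_act:]))
    v_peak = V[i_peak]
    level = v_peak - 0.95 * (v_peak - v_rest)
    t_rep, _ = _first_downward_crossing(t, V, level, i_peak)
    if t_rep is None:
        return None
    return float(t_rep - t_act)


def classify_behavior(trace: APTrace) -> BehaviorLabel:
    """Assign the AP behavior label from interior local extrema counts."""
    if trace.t[-1] - trace.stim.onset < 1000.0 - 1e-9:
        raise ValueError("classification requires a trace extending to "
                         ">= 1000 ms after stimulus onset")
    t_max, _, t_min, _ = _extrema(trace)
    n_max, n_min = t_max.size, t_min.size

    if n_min == 0 and n_max >= 1:
        if t_max[0] > SPIKE_TIME_LIMIT:
            return BehaviorLabel(1)
        return BehaviorLabel(2)
    oscillatory = n_min >= 2 or (
        n_max == 2 and n_min == 1 and t_max[0] > SPIKE_TIME_LIMIT)
    if oscillatory:
        return BehaviorLabel(3, classify_oscillatory_subtype(trace))
    return BehaviorLabel(4)


def classify_oscillatory_subtype(trace: APTrace) -> str:
    """Partition oscillatory APs by voltage 1000 ms after stimulus onset:
    < -75 mV back at rest (3A), > -25 mV repolarization failure (3B),
    low-voltage oscillations otherwise (3C)."""
    v = float(trace.state_at(trace.stim.onset + 1000.0)[0])
    if v < -75.0:
        return "3A"
    if v > -25.0:
        return "3B"
    return "3C"
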