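"""Shared fixtures: expensive nominal-model simulations are session-scoped
so the suite pays for each of them once."""

import numpy as np
import pytest

import cardiouq as cq


@pytest.fixture(scope="session")
def nominal():
    return cq.nominal_parameters()


@pytest.fixture(scope="session")
def nominal_threshold(nominal):
    return cq.find_threshold(nominal)


@pytest.fixture(scope="session")
def nominal_trace(nominal, nominal_threshold):
    stim = cq.StimulusProtocol(amplitude=1.1 * nominal_threshold)
    return cq.simulate_ap(nominal, stim, duration=1000.0)


@pytest.fixture(scope="session")
def paced_beats(nominal):
    """Eleven beats of 1 Hz pacing (ten conditioning + one analyzed)."""
    return cq.pace(nominal, bcl=1000.0, n_beats=11)


def synthetic_trace(t, V, stim_amplitude=1.0, onset=0.0, duration=0.5):
    """An APTrace carrying a prescribed voltage course (gates at rest)."""
    t = np.asarray(t, dtype=float)
    states = np.zeros((t.size, 7))
    states[:, 0] = V
    stim = cq.StimulusProtocol(amplitude=stim_amplitude, onset=onset,
                               duration=duration)
    return cq.APTrace(t=t, states=states, params=cq.nominal_parameters(),
                      stim=stim, dt_out=float(t[1] - t[0]))
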