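"""Gating functions, currents, right-hand side and initial conditions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiouq as cq
from cardiouq.model import CURRENT_NAMES
from cardiouq.parameters import GATES

# Independently hand-evaluated sigmoid values at V = -85 mV with nominal
# parameters (frozen oracle).
M_INF_REST = 0.0066725734
H_INF_REST = 0.7431478912
# Resting I_Na from direct evaluation of the current equation at the
# steady-state gates (all other currents vanish at V = EK).
INA_REST = -0.0002953270


@pytest.fixture(scope="module")
def p():
    return cq.nominal_parameters()


class TestGateSteadyState:
    def test_midpoint_is_half(self, p):
        for name, spec in GATES.items():
            E = p[{"m": "Em", "h": "Eh", "z": "Ez", "r": "Er", "s": "Es",
                   "d": "Ed", "f": "Ef", "xr": "Exr", "y": "Ey",
                   "xs": "Exs"}[name]]
            assert cq.gate_steady_state(E, name, p) == pytest.approx(0.5)

    def test_limits(self, p):
        for name, spec in GATES.items():
            hi = cq.gate_steady_state(1e4, name, p)
            lo = cq.gate_steady_state(-1e4, name, p)
            if spec.kind == "activation":
                assert hi == pytest.approx(1.0) and lo == pytest.approx(0.0)
            else:
                assert hi == pytest.approx(0.0) and lo == pytest.approx(1.0)

    def test_rest_values_match_hand_oracle(self, p):
        assert cq.gate_steady_state(-85.0, "m", p) == pytest.approx(
            M_INF_REST, rel=1e-6)
        assert cq.gate_steady_state(-85.0, "h", p) == pytest.approx(
            H_INF_REST, rel=1e-6)

    def test_monotone_on_grid(self, p):
        V = np.linspace(-120.0, 60.0, 361)
        for name, spec in GATES.items():
            y = cq.gate_steady_state(V, name, p)
            assert np.all((y > 0) & (y < 1))
            d = np.diff(y)
            if spec.kind == "activation":
                assert np.all(d >= 0)
            else:
                assert np.all(d <= 0)

    def test_unknown_gate_errors(self, p):
        with pytest.raises(KeyError):
            cq.gate_steady_state(-85.0, "q", p)


class TestTauH:
    def test_midpoint_cancellation(self, p):
        assert cq.tau_h(p.Eh, p) == pytest.approx(p.tau_h0, rel=1e-12)

    def test_one_slope_up(self, p):
        expected = 2 * p.tau_h0 * math.exp(p.delta_h) / (1 + math.e)
        assert cq.tau_h(p.Eh + p.kh, p) == pytest.approx(expected, rel=1e-12)

    def test_limit_negative_v(self, p):
        assert cq.tau_h(-1e4, p) == pytest.approx(0.0, abs=1e-200)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(V=st.floats(-200, 100))
    def test_strictly_positive_in_physiological_range(self, V):
        assert cq.tau_h(V, cq.nominal_parameters()) > 0


class TestIonicCurrents:
    def test_zero_driving_force_at_ek(self, p):
        state = [p.EK, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        cur = cq.ionic_currents(state, p)
        for name in ("IK1", "Ito", "IKr", "IKs"):
            assert cur[name] == 0.0

    def test_closed_m_gate_kills_ina(self, p):
        cur = cq.ionic_currents([20.0, 0.0, 0.9, 0.5, 0.5, 0.5, 0.5], p)
        assert cur["INa"] == 0.0

    def test_resting_currents_match_hand_oracle(self, p):
        y0 = cq.initial_conditions(p)
        cur = cq.ionic_currents(y0, p)
        assert cur["INa"] == pytest.approx(INA_REST, rel=1e-5)
        for name in ("IK1", "Ito", "IKr", "IKs"):
            assert cur[name] == 0.0
        assert abs(cur["ICaL"]) < 1e-6  # d gate is essentially closed

    def test_instantaneous_gates_follow_supplied_v(self, p):
        # I_K1 depends on V only through z_inf(V) and the driving force
        z40 = cq.gate_steady_state(-40.0, "z", p)
        cur = cq.ionic_currents([-40.0, 0, 1, 1, 1, 0, 0], p)
        assert cur["IK1"] == pytest.approx(p.gK1 * z40 * (-40.0 + 85.0))


class TestRHS:
    def test_gate_fixed_point(self, p):
        V = -30.0
        state = [V] + [cq.gate_steady_state(V, g, p)
                       for g in ("m", "h", "s", "f", "xr", "xs")]
        dy = cq.rhs(0.0, state, p, stim=0.0)
        assert np.allclose(dy[1:], 0.0, atol=1e-14)

    def test_capacitor_equation(self, p):
        # all conductances zero -> dV/dt = I_stim / Cm
        p0 = p.replace(gNa=1e-300, gK1=1e-300, gto=1e-300, gCaL=1e-300,
                       gKr=1e-300, gKs=1e-300)
        dy = cq.rhs(0.0, [-50.0, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2], p0, stim=3.0)
        assert dy[0] == pytest.approx(3.0, abs=1e-12)

    def test_consistency_with_currents(self, p):
        y0 = cq.initial_conditions(p)
        dy = cq.rhs(0.0, y0, p, stim=0.0)
        total = sum(cq.ionic_currents(y0, p).values())
        assert dy[0] == pytest.approx(-total, rel=1e-12)

    def test_callable_stimulus(self, p):
        y0 = cq.initial_conditions(p)
        dy_const = cq.rhs(1.0, y0, p, stim=2.0)
        dy_fn = cq.rhs(1.0, y0, p, stim=lambda t: 2.0 * (t < 5))
        assert np.array_equal(dy_const, dy_fn)

    def test_nonfinite_state_rejected(self, p):
        with pytest.raises(ValueError):
            cq.rhs(0.0, [np.nan, 0, 0, 0, 0, 0, 0], p)


class TestInitialConditions:
    def test_resting_voltage_is_ek(self, p):
        y0 = cq.initial_conditions(p)
        assert y0[0] == -85.0

    def test_gates_start_at_steady_state(self, p):
        y0 = cq.initial_conditions(p)
        assert y0[1] == pytest.approx(M_INF_REST, rel=1e-6)
        assert y0[2] == pytest.approx(H_INF_REST, rel=1e-6)
        dy = cq.rhs(0.0, y0, p, stim=0.0)
        assert np.all(dy[1:] == 0.0)

    def test_tracks_perturbed_ek(self, p):
        p2 = p.replace(EK=-80.0)
        y0 = cq.initial_conditions(p2)
        assert y0[0] == -80.0
        assert y0[1] == pytest.approx(
            cq.gate_steady_state(-80.0, "m", p2), rel=1e-12)


def test_current_names_cover_six_currents():
    assert len(CURRENT_NAMES) == 6
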