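"""Simulation protocols: single AP, threshold bisection, pacing,
restitution, and solver robustness."""

import numpy as np
import pytest

import cardiouq as cq
from cardiouq.protocols import SolverSettings, ThresholdError


class TestSimulateAP:
    def test_resting_state_is_near_stationary(self, nominal):
        stim = cq.StimulusProtocol(amplitude=0.0)
        tr = cq.simulate_ap(nominal, stim, duration=1000.0)
        assert np.all(np.abs(tr.V - nominal.EK) < 1.0)

    def test_nominal_ap_is_spike_and_dome(self, nominal_trace):
        q = cq.extract_qois(nominal_trace)
        assert q.notch_min is not None and q.notch_max is not None
        assert q.notch_min < q.notch_max
        assert cq.classify_behavior(nominal_trace).major == 4

    def test_gates_stay_in_unit_interval(self, nominal_trace):
        gates = nominal_trace.states[:, 1:]
        assert gates.min() >= 0.0 and gates.max() <= 1.0

    def test_output_grid_independence(self, nominal, nominal_threshold):
        stim = cq.StimulusProtocol(amplitude=1.1 * nominal_threshold)
        apd = {}
        for dt_out in (0.05, 0.1):
            tr = cq.simulate_ap(nominal, stim, duration=600.0, dt_out=dt_out)
            apd[dt_out] = cq.extract_qois(tr).apd
        assert abs(apd[0.05] - apd[0.1]) < 0.2

    def test_solver_tolerance_convergence(self, nominal, nominal_threshold):
        stim = cq.StimulusProtocol(amplitude=1.1 * nominal_threshold)
        qois = {}
        for f in (1.0, 0.1):
            tr = cq.simulate_ap(
                nominal, stim, duration=600.0,
                solver=SolverSettings(rtol=1e-6 * f, atol=1e-8 * f))
            qois[f] = cq.extract_qois(tr)
        # 10x tighter tolerances move every defined QOI by < 0.5%
        for name in ("max_upstroke_velocity", "apa", "apd", "notch_min",
                     "notch_max"):
            a, b = getattr(qois[1.0], name), getattr(qois[0.1], name)
            assert abs(a - b) / abs(b) < 0.005
        assert abs(qois[1.0].apd - qois[0.1].apd) < 0.1

    def test_bit_identical_reruns(self, nominal, nominal_threshold):
        stim = cq.StimulusProtocol(amplitude=1.1 * nominal_threshold)
        a = cq.simulate_ap(nominal, stim, duration=300.0)
        b = cq.simulate_ap(nominal, stim, duration=300.0)
        assert np.array_equal(a.states, b.states)

    def test_duration_must_cover_stimulus(self, nominal):
        with pytest.raises(ValueError):
            cq.simulate_ap(nominal, cq.StimulusProtocol(amplitude=1.0,
                                                        onset=90.0),
                           duration=50.0)


class TestStimulusProtocol:
    def test_square_pulse_values(self):
        s = cq.StimulusProtocol(amplitude=2.0, onset=1.0, duration=0.5)
        assert s.current(0.5) == 0.0
        assert s.current(1.2) == 2.0
        assert s.current(1.6) == 0.0

    def test_pacing_pulses_repeat(self):
        s = cq.StimulusProtocol(amplitude=2.0, duration=0.5, period=100.0)
        assert s.current(100.2) == 2.0 and s.current(50.0) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            cq.StimulusProtocol(amplitude=-1.0)
        with pytest.raises(ValueError):
            cq.StimulusProtocol(amplitude=1.0, duration=0.0)
        with pytest.raises(ValueError):
            cq.StimulusProtocol(amplitude=1.0, duration=2.0, period=1.0)


class TestFindThreshold:
    def test_bracketing_postcondition(self, nominal, nominal_threshold):
        from cardiouq.protocols import _depolarizes
        assert _depolarizes(nominal, 1.1 * nominal_threshold, 0.5,
                            SolverSettings())
        assert not _depolarizes(nominal, 0.9 * nominal_threshold, 0.5,
                                SolverSettings())

    def test_monotone_in_gna(self, nominal):
        thr = [cq.find_threshold(nominal.replace(gNa=f * nominal.gNa))
               for f in (0.5, 1.0, 2.0)]
        assert thr[0] >= thr[1] >= thr[2]

    def test_bracket_failure_identifies_params(self, nominal):
        weak = nominal.replace(gNa=1e-6)
        with pytest.raises(ThresholdError):
            cq.find_threshold(weak, search_hi=1.0)


class TestPace:
    def test_single_beat_matches_simulate_ap(self, nominal,
                                             nominal_threshold):
        amp = 1.1 * nominal_threshold
        beat = cq.pace(nominal, bcl=1000.0, n_beats=1, amplitude=amp)[0]
        direct = cq.simulate_ap(nominal, cq.StimulusProtocol(amplitude=amp),
                                duration=1000.0)
        assert np.array_equal(beat.states, direct.states)

    def test_approaches_limit_cycle(self, paced_beats):
        apd10 = cq.apd95(paced_beats[9])
        apd11 = cq.apd95(paced_beats[10])
        assert abs(apd11 - apd10) / apd10 < 0.01

    def test_paced_ap_differs_from_first_beat(self, paced_beats):
        q1 = cq.extract_qois(paced_beats[0])
        q11 = cq.extract_qois(paced_beats[10])
        assert abs(q1.apd - q11.apd) > 1.0

    def test_validation(self, nominal):
        with pytest.raises(ValueError):
            cq.pace(nominal, bcl=50.0)


class TestDynamicRestitution:
    def test_restitution_curve(self, nominal, nominal_threshold):
        table = cq.dynamic_restitution(
            nominal, [1000.0, 800.0, 600.0, 400.0], beats_per_bcl=20,
            amplitude=1.1 * nominal_threshold)
        assert table["captured"].all()
        apd = table["APD95"].to_numpy()
        assert np.all(np.diff(apd) <= 0)  # shorter BCL, shorter APD
        # DI + APD95 = BCL by definition for captured rows
        np.testing.assert_allclose(
            table["DI"] + table["APD95"], table["BCL"], rtol=1e-12)

    def test_long_bcl_limit_near_paced_value(self, nominal, paced_beats,
                                             nominal_threshold):
        table = cq.dynamic_restitution(
            nominal, [1000.0], beats_per_bcl=20,
            amplitude=1.1 * nominal_threshold)
        assert table["APD95"].iloc[0] == pytest.approx(
            cq.apd95(paced_beats[10]), rel=0.01)

    def test_schedule_must_decrease(self, nominal):
        with pytest.raises(ValueError):
            cq.dynamic_restitution(nominal, [400.0, 800.0])
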