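"""Uncertainty characterization and Monte Carlo propagation."""

import math

import numpy as np
import pandas as pd
import pytest

import cardiouq as cq
from cardiouq import uq


@pytest.fixture(scope="module")
def nominal_p():
    return cq.nominal_parameters()


class TestDistributions:
    def test_lognormal_mean_is_nominal_exactly(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.07)
        for name in ("gNa", "km", "tau_xr", "delta_h"):
            mu = math.log(nominal_p[name]) - 0.5 * spec.sigma_hat ** 2
            analytic_mean = math.exp(mu + 0.5 * spec.sigma_hat ** 2)
            assert analytic_mean == pytest.approx(nominal_p[name], rel=1e-12)

    def test_normal_sd_is_sigma_times_reference(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.01)
        assert spec.sd("Em") == pytest.approx(1.0)   # 0.01 * 100 mV
        assert spec.sd("Ed") == pytest.approx(1.0)

    def test_degenerate_at_sigma_zero(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.0)
        for name in ("gNa", "Em", "tau_h0"):
            for q in (0.01, 0.5, 0.99):
                assert spec.ppf(name, q) == nominal_p[name]

    def test_negative_sigma_rejected(self, nominal_p):
        with pytest.raises(ValueError):
            uq.build_distributions(nominal_p, -0.1)

    def test_family_assignment(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.05,
                                      overrides=("Eh", "delta_h"))
        assert spec.family("Em") == "normal"
        assert spec.family("gNa") == "lognormal"
        assert spec.family("ENa") == "fixed"
        assert spec.family("Eh") == "fixed"      # override
        assert spec.family("delta_h") == "fixed"
        assert "Eh" not in spec.free_names
        assert len(spec.free_names) == 31


class TestSampling:
    def test_same_seed_identical(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.03)
        a = uq.sample_parameters(spec, 500, seed=5)
        b = uq.sample_parameters(spec, 500, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_fixed_columns_constant(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.05, overrides=("Er",))
        sm = uq.sample_parameters(spec, 200, seed=1)
        df = sm.to_frame()
        for name in ("ENa", "EK", "ECa", "Er"):
            assert df[name].nunique() == 1
            assert df[name].iloc[0] == nominal_p[name]

    def test_moments_match_law(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.05)
        sm = uq.sample_parameters(spec, 100_000, seed=9)
        df = sm.to_frame()
        # lognormal: sample mean -> p_nom within MC error
        assert df["gNa"].mean() == pytest.approx(12.0, rel=0.005)
        # lognormal moment identity: var / p_nom^2 ~ sigma^2 + O(sigma^4)
        assert df["gNa"].var() / 12.0 ** 2 == pytest.approx(
            0.05 ** 2, rel=0.05)
        # normal: sd = sigma * R
        assert df["Em"].std() == pytest.approx(5.0, rel=0.02)

    def test_sample_sd_of_em_at_one_percent(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.01)
        sm = uq.sample_parameters(spec, 50_000, seed=2)
        assert sm.to_frame()["Em"].std() == pytest.approx(1.0, rel=0.03)

    def test_positivity_invariants_hold(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.10)
        sm = uq.sample_parameters(spec, 5000, seed=3)
        for i in range(0, 5000, 997):
            sm.row(i)  # ParameterSet constructor enforces positivity

    def test_csv_round_trip(self, nominal_p, tmp_path):
        spec = uq.build_distributions(nominal_p, 0.02)
        sm = uq.sample_parameters(spec, 50, seed=4)
        path = tmp_path / "samples.csv"
        sm.to_csv(path)
        back = uq.SampleMatrix.from_csv(path)
        assert np.array_equal(back.values, sm.values)  # bit-for-bit


class TestPropagation:
    def test_sigma_zero_gives_zero_cov(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.0)
        res = uq.propagate(spec, 6, seed=0)
        for name in ("threshold", "apd", "apa"):
            assert res.summary.loc[name, "cov_pct"] == pytest.approx(
                0.0, abs=1e-9)
        assert res.n_failed == 0

    def test_failures_recorded_not_fatal(self, nominal_p):
        # an invalid row must be flagged, never abort the batch
        spec = uq.build_distributions(nominal_p, 0.0)
        sm = uq.sample_parameters(spec, 3, seed=0)
        vals = sm.values.copy()
        vals[1, 0] = -1.0  # negative conductance violates the invariants
        table = uq.evaluate_rows(vals)
        assert bool(table.loc[1, "sim_failed"])
        assert not table.loc[0, "sim_failed"]
        assert np.isnan(table.loc[1, "apd"])

    def test_summary_reports_undefined_fraction(self):
        table = pd.DataFrame({
            "apd": [100.0, 110.0, np.nan, 105.0],
            "sim_failed": [False, False, False, False],
        })
        res = uq.summarize_qois(table, qoi_names=("apd",))
        assert res.summary.loc["apd", "n_defined"] == 3
        assert res.summary.loc["apd", "frac_undefined"] == pytest.approx(0.25)

    def test_convergence_rule_n_vs_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100.0, 1.0, 200_000)
        assert uq._converged(x)
        assert not uq._converged(rng.normal(100.0, 30.0, 8))

    def test_histogram_convention(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.0)
        res = uq.propagate(spec, 6, seed=0)
        counts, edges = res.histograms["apd"]
        assert counts.size == 50
        mean = res.summary.loc["apd", "mean"]
        assert edges[0] == pytest.approx(0.6 * mean)
        assert edges[-1] == pytest.approx(1.4 * mean)


class TestBehaviorProbabilities:
    def test_fractions_partition(self):
        table = pd.DataFrame({
            "behavior": ["4", "4", "1", "3A", "3B", "4"],
            "behavior_major": [4, 4, 1, 3, 3, 4],
            "sim_failed": [False] * 6,
        })
        bp = uq.behavior_probabilities(None, 0, table=table)
        majors = bp.loc[["1", "2", "3", "4"], "fraction"]
        assert majors.sum() == pytest.approx(1.0)
        subs = bp.loc[["3A", "3B", "3C"], "fraction"]
        assert subs.sum() == pytest.approx(bp.loc["3", "fraction"])
        assert bp.loc["3B", "count"] == 1

    def test_small_n_rejected_when_sampling(self, nominal_p):
        spec = uq.build_distributions(nominal_p, 0.01)
        with pytest.raises(ValueError):
            uq.behavior_probabilities(spec, 10, seed=0)
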