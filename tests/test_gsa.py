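"""Sobol estimators and Morris screening against analytic oracles."""

import numpy as np
import pytest

import cardiouq as cq
from cardiouq import gsa, uq


@pytest.fixture(scope="module")
def spec():
    return uq.build_distributions(cq.nominal_parameters(), 0.05)


def _standardized(spec, design, names):
    """Design columns transformed to zero-mean unit-variance variables."""
    out = []
    for name in names:
        col = design.matrix.values[:, list(spec.nominal.to_dict()).index(name)]
        if spec.family(name) == "lognormal":
            # standardize on the log scale: exactly normal by construction
            import math
            mu = math.log(spec.nominal[name]) - 0.5 * spec.sigma_hat ** 2
            out.append((np.log(col) - mu) / spec.sigma_hat)
        else:
            out.append((col - spec.mean(name)) / spec.sd(name))
    return out


class TestSaltelliDesign:
    def test_row_count_arithmetic(self, spec):
        des = gsa.saltelli_design(spec, 256, seed=0,
                                  param_subset=("gNa", "Em", "kh"))
        assert des.n_rows == 256 * (3 + 2)
        assert des.matrix.values.shape == (des.n_rows, 36)

    def test_rows_satisfy_positivity(self, spec):
        des = gsa.saltelli_design(spec, 128, seed=1)
        for i in range(0, des.n_rows, 503):
            des.matrix.row(i)  # constructor enforces invariants

    def test_unsampled_columns_stay_nominal(self, spec):
        des = gsa.saltelli_design(spec, 64, seed=2,
                                  param_subset=("gNa", "Em"))
        df = des.matrix.to_frame()
        assert df["kh"].nunique() == 1
        assert df["kh"].iloc[0] == spec.nominal.kh

    def test_deterministic_for_seed(self, spec):
        a = gsa.saltelli_design(spec, 64, seed=3, param_subset=("gNa",))
        b = gsa.saltelli_design(spec, 64, seed=3, param_subset=("gNa",))
        assert np.array_equal(a.matrix.values, b.matrix.values)

    def test_empty_subset_rejected(self, spec):
        with pytest.raises(ValueError):
            gsa.saltelli_design(spec, 64, seed=0, param_subset=())


class TestSobolIndices:
    def test_linear_function_matches_analytic(self, spec):
        des = gsa.saltelli_design(spec, 1024, seed=5,
                                  param_subset=("gNa", "Em"))
        z1, z2 = _standardized(spec, des, ("gNa", "Em"))
        y = 1.0 * z1 + 2.0 * z2   # S1 = ST = (0.2, 0.8)
        res = gsa.sobol_indices(des, y, qoi="linear", seed=0)
        assert res.table.loc["gNa", "S1"] == pytest.approx(0.2, abs=0.05)
        assert res.table.loc["Em", "S1"] == pytest.approx(0.8, abs=0.05)
        assert res.table.loc["gNa", "ST"] == pytest.approx(0.2, abs=0.05)
        assert res.table.loc["Em", "ST"] == pytest.approx(0.8, abs=0.05)

    def test_pure_interaction(self, spec):
        des = gsa.saltelli_design(spec, 1024, seed=6,
                                  param_subset=("gNa", "Em"))
        z1, z2 = _standardized(spec, des, ("gNa", "Em"))
        res = gsa.sobol_indices(des, z1 * z2, qoi="interaction", seed=0)
        for name in ("gNa", "Em"):
            assert res.table.loc[name, "S1"] == pytest.approx(0.0, abs=0.1)
            assert res.table.loc[name, "ST"] == pytest.approx(1.0, abs=0.15)

    def test_constant_output_gives_zero_indices(self, spec):
        des = gsa.saltelli_design(spec, 128, seed=7, param_subset=("gNa",))
        res = gsa.sobol_indices(des, np.full(des.n_rows, 3.5), seed=0)
        assert res.variance == 0.0
        assert (res.table[["S1", "ST"]] == 0.0).all().all()

    def test_monte_carlo_convergence(self, spec):
        errs = {}
        for base_n in (256, 1024):
            des = gsa.saltelli_design(spec, base_n, seed=8,
                                      param_subset=("gNa", "Em"))
            z1, z2 = _standardized(spec, des, ("gNa", "Em"))
            res = gsa.sobol_indices(des, z1 + 2.0 * z2, seed=0)
            errs[base_n] = abs(res.table.loc["Em", "S1"] - 0.8)
        assert errs[1024] <= errs[256] + 0.01

    def test_undefined_values_fail_loudly(self, spec):
        des = gsa.saltelli_design(spec, 64, seed=9, param_subset=("gNa",))
        y = np.ones(des.n_rows)
        y[5] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            gsa.sobol_indices(des, y)


class TestMorris:
    def test_inert_parameter_has_zero_mu_star(self, spec):
        def ev(vals):
            return vals[:, 0]  # depends on gNa only
        res = gsa.morris_screen(spec, ev, n_trajectories=25, seed=10,
                                param_subset=("gNa", "Em", "kh"))
        assert res.table.loc["Em", "mu_star"] == 0.0
        assert res.table.loc["kh", "mu_star"] == 0.0
        assert res.table.loc["gNa", "mu_star"] > 0.0
        assert set(res.excluded) == {"Em", "kh"}
        assert res.influential == ("gNa",)

    def test_linear_effect_has_zero_spread(self, spec):
        from scipy.stats import norm

        def ev(vals):
            # linear in the unit-hypercube coordinate of Em
            z = (vals[:, 1] - spec.mean("Em")) / spec.sd("Em")
            return 3.0 * norm.cdf(z)
        res = gsa.morris_screen(spec, ev, n_trajectories=25, seed=11,
                                param_subset=("Em", "gNa"))
        # every elementary effect of a map linear in u equals its slope
        assert res.table.loc["Em", "mu_star"] == pytest.approx(3.0, rel=1e-6)
        assert res.table.loc["Em", "sigma"] == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_has_positive_spread(self, spec):
        def ev(vals):
            z = (vals[:, 1] - spec.mean("Em")) / spec.sd("Em")
            return z ** 2
        res = gsa.morris_screen(spec, ev, n_trajectories=25, seed=12,
                                param_subset=("Em", "gNa"))
        assert res.table.loc["Em", "mu_star"] > 0.0
        assert res.table.loc["Em", "sigma"] > 0.0

    def test_nan_trajectories_discarded(self, spec):
        def ev(vals):
            y = vals[:, 0].astype(float).copy()
            y[0] = np.nan  # poison the first trajectory
            return y
        res = gsa.morris_screen(spec, ev, n_trajectories=25, seed=13,
                                param_subset=("gNa",))
        assert res.table.attrs["n_discarded_trajectories"] == 1
        assert res.n_trajectories == 24

    def test_too_few_trajectories_rejected(self, spec):
        with pytest.raises(ValueError):
            gsa.morris_screen(spec, lambda v: v[:, 0], n_trajectories=5)
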