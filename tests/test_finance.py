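"""DCF engine, MSPD solver, triangular Monte-Carlo and density fit."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrnaplant.errors import InvalidInputError, NonConvergenceError
from mrnaplant.finance import (FinanceParams, TriangularParam,
                               annual_cash_flow, fit_mspd_density,
                               macrs_schedule, monte_carlo_mspd, npv,
                               sample_triangular, solve_mspd, tornado,
                               venture_npv)
from mrnaplant.scenario import make_mspd_rebuild


class TestMacrs:
    def test_standard_fractions(self):
        assert macrs_schedule(100.0) == pytest.approx(
            [20.0, 32.0, 19.2, 11.52, 11.52, 5.76])

    def test_conserves_fci(self):
        fci = 18_865_139.62
        assert sum(macrs_schedule(fci)) == pytest.approx(fci, rel=1e-12)

    def test_zero(self):
        assert macrs_schedule(0.0) == [0.0] * 6


class TestCashFlow:
    def test_no_tax(self):
        assert annual_cash_flow(100.0, 40.0, 5.0, 0.0) == pytest.approx(60.0)

    def test_hand_arithmetic(self):
        assert annual_cash_flow(100.0, 50.0, 10.0, 0.21) \
            == pytest.approx(41.6)

    def test_zero_margin(self):
        assert annual_cash_flow(50.0, 50.0, 0.0, 0.21) == 0.0


class TestNpv:
    def test_zero_rate_is_sum(self):
        flows = [-100.0, 30.0, 30.0, 30.0, 30.0]
        assert npv(flows, 0.0) == pytest.approx(sum(flows))

    def test_forced_zero(self):
        assert npv([-100.0, 110.0], 0.10) == pytest.approx(0.0, abs=1e-9)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=15),
           st.floats(0.0, 0.5))
    def test_matches_brute_force_loop(self, flows, rate):
        expected = 0.0
        for year, flow in enumerate(flows):
            expected += flow / (1.0 + rate) ** year
        assert npv(flows, rate) == pytest.approx(expected, rel=1e-9,
                                                 abs=1e-6)

    def test_invalid_rate(self):
        with pytest.raises(InvalidInputError):
            npv([1.0], -1.0)


class TestSolveMspd:
    def test_npv_zero_at_solution(self, baseline):
        from mrnaplant.scenario import build_costs
        bd, fin = build_costs(baseline)
        price = solve_mspd(bd.COM_d, bd.FCI, bd.TCI, fin)
        assert abs(venture_npv(price, bd.COM_d, bd.FCI, bd.TCI, fin)) < 1.0

    def test_degenerate_scenario_hits_floor(self):
        fin = FinanceParams()
        assert solve_mspd(0.0, 0.0, 0.0, fin) == 0.01

    def test_monotone_in_material_cost(self, baseline):
        from mrnaplant.scenario import build_costs
        bd, fin = build_costs(baseline)
        p0 = solve_mspd(bd.COM_d, bd.FCI, bd.TCI, fin)
        p1 = solve_mspd(bd.COM_d * 1.1, bd.FCI, bd.TCI, fin)
        assert p1 > p0

    @given(com=st.floats(1e6, 5e8), fci=st.floats(1e6, 5e7),
           bump=st.floats(1.01, 1.5))
    def test_monotone_random_scenarios(self, com, fci, bump):
        fin = FinanceParams()
        tci = fci / 0.85
        assert solve_mspd(com * bump, fci, tci, fin) \
            >= solve_mspd(com, fci, tci, fin)


class TestTriangular:
    def test_degenerate_is_constant(self):
        p = TriangularParam("x", ("finance", "discount_rate"), 0.1,
                            low_conversion=0.0, high_conversion=0.0)
        rng = np.random.default_rng(0)
        assert {sample_triangular(p, rng) for _ in range(10)} == {0.1}

    def test_mean_and_bounds(self):
        p = TriangularParam("price", ("material", "X"), 100.0,
                            low_conversion=-0.10, high_conversion=0.30)
        lo, mode, hi = p.resolved
        rng = np.random.default_rng(123)
        draws = np.array([sample_triangular(p, rng) for _ in range(100_000)])
        assert draws.min() >= lo and draws.max() <= hi
        mean = (lo + mode + hi) / 3.0
        var = (lo**2 + mode**2 + hi**2 - lo*mode - lo*hi - mode*hi) / 18.0
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - mean) < 3 * se


class TestMonteCarlo:
    def degenerate_priors(self):
        return [TriangularParam("x", ("finance", "tax_rate"), 0.21,
                                low_conversion=0.0, high_conversion=0.0)]

    def test_degenerate_priors_reproduce_baseline(self, baseline):
        rebuild = make_mspd_rebuild(baseline)
        mc = monte_carlo_mspd(rebuild, self.degenerate_priors(), n=100,
                              seed=4)
        assert np.all(mc.samples == mc.baseline)

    def test_same_seed_identical(self, baseline):
        rebuild = make_mspd_rebuild(baseline)
        a = monte_carlo_mspd(rebuild, baseline.priors, n=150, seed=7)
        b = monte_carlo_mspd(rebuild, baseline.priors, n=150, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.median == b.median

    def test_cross_seed_consistency(self, baseline):
        """The median of one run lies inside the 1-99 percentile band of an
        independent run (stochastic self-consistency)."""
        rebuild = make_mspd_rebuild(baseline)
        a = monte_carlo_mspd(rebuild, baseline.priors, n=600, seed=11)
        b = monte_carlo_mspd(rebuild, baseline.priors, n=600, seed=12)
        assert b.percentiles[1] < a.median < b.percentiles[99]

    def test_percentiles_monotone(self, baseline):
        rebuild = make_mspd_rebuild(baseline)
        mc = monte_carlo_mspd(rebuild, baseline.priors, n=200, seed=3)
        levels = sorted(mc.percentiles)
        values = [mc.percentiles[p] for p in levels]
        assert values == sorted(values)

    def test_too_few_iterations_rejected(self, baseline):
        with pytest.raises(InvalidInputError):
            monte_carlo_mspd(make_mspd_rebuild(baseline), [], n=10, seed=0)


class TestTornado:
    def test_degenerate_prior_zero_swing(self, baseline):
        rebuild = make_mspd_rebuild(baseline)
        swings = tornado(rebuild, self.priors_degenerate())
        name, lo, hi = swings[0]
        assert lo == hi

    def priors_degenerate(self):
        return [TriangularParam("x", ("finance", "tax_rate"), 0.21,
                                low_conversion=0.0, high_conversion=0.0)]

    def test_swing_signs(self, baseline):
        rebuild = make_mspd_rebuild(baseline)
        by_name = {p.name: p for p in baseline.priors}
        for name in ("HIC resin price", "Discount rate"):
            _, lo, hi = tornado(rebuild, [by_name[name]])[0]
            assert hi > lo   # costlier inputs / dearer capital raise MSPD

    def test_largest_material_swing_is_linearization_enzyme(self, baseline):
        rebuild = make_mspd_rebuild(baseline)
        materials = [p for p in baseline.priors if p.target[0] == "material"]
        swings = tornado(rebuild, materials)
        assert swings[0][0] == "Linearization restriction enzyme price"


class TestDensityFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        c_true, m_true = 0.05, 1.4
        samples = rng.lognormal(mean=np.log(m_true), sigma=c_true,
                                size=20_000)
        fit = fit_mspd_density(samples)
        assert fit["scale"] == pytest.approx(m_true, rel=0.05)
        assert fit["width"] == pytest.approx(c_true, rel=0.05)
        assert fit["amplitude"] == pytest.approx(1.0, rel=0.05)
        assert fit["offset"] == pytest.approx(0.0, abs=0.05)

    def test_fitted_curve_normalises(self):
        rng = np.random.default_rng(8)
        samples = rng.lognormal(mean=np.log(1.38), sigma=0.04, size=10_000)
        fit = fit_mspd_density(samples)
        from mrnaplant.finance import _density_form
        xs = np.linspace(samples.min(), samples.max(), 2000)
        integral = np.trapezoid(
            _density_form(xs, 0.0, fit["amplitude"], fit["width"],
                          fit["scale"]), xs)
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_constant_samples_rejected(self):
        with pytest.raises(NonConvergenceError):
            fit_mspd_density(np.full(2000, 1.38))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_mspd_density(np.ones(10))
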