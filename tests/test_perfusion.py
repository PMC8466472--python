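"""Upstream perfusion: dimensionless criteria and Monod steady states."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mrnaplant.errors import InvalidInputError, NonConvergenceError
from mrnaplant.perfusion import (MixingSpec, MonodParams, PerfusionSpec,
                                 chemostat_steady_state, froude, mixing_time,
                                 perfusion_rhs, perfusion_steady_state,
                                 reynolds)
from mrnaplant._units import rpm_to_hz

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def spec(n=1.0, d_imp=0.1, d_ves=0.2, rho=1000.0, mu=1e-3, p=None, v=None):
    return MixingSpec(rotation_rate=n, impeller_diameter=d_imp,
                      vessel_diameter=d_ves, fluid_density=rho,
                      fluid_viscosity=mu, agitation_power=p, fluid_volume=v)


class TestFroude:
    @pytest.mark.parametrize("n, d, expected", [
        (rpm_to_hz(200.0), 0.23, 0.26),   # agitation design point
        (0.0, 0.23, 0.0),                 # no rotation
        (1.0, 9.81, 1.0),                 # g cancellation
    ])
    def test_values(self, n, d, expected):
        assert froude(spec(n=n, d_imp=d / 2, d_ves=d)) == pytest.approx(
            expected, abs=5e-3)

    def test_invalid_diameter_rejected(self):
        with pytest.raises(InvalidInputError):
            spec(d_ves=-1.0)

    @given(n=positive, d=positive, scale=st.floats(min_value=0.5,
                                                   max_value=4.0))
    def test_homogeneity(self, n, d, scale):
        base = froude(spec(n=n, d_imp=d / 2, d_ves=d))
        assert froude(spec(n=scale * n, d_imp=d / 2, d_ves=d)) \
            == pytest.approx(scale ** 2 * base, rel=1e-9)
        assert froude(spec(n=n, d_imp=d / 2, d_ves=scale * d)) \
            == pytest.approx(scale * base, rel=1e-9)


class TestReynolds:
    def test_direct_evaluation(self):
        s = spec(n=rpm_to_hz(200.0), d_imp=0.23 / 2, d_ves=0.23,
                 rho=1000.0, mu=1e-3)
        assert reynolds(s, diameter="vessel") == pytest.approx(176_333, abs=1)

    def test_diameter_power_law(self):
        s1 = spec(d_imp=0.05, d_ves=0.4)
        s2 = spec(d_imp=0.10, d_ves=0.4)
        assert reynolds(s2) == pytest.approx(4 * reynolds(s1), rel=1e-12)

    def test_identity_case(self):
        assert reynolds(spec(n=1.0, d_imp=1.0, d_ves=1.0, rho=2.5,
                             mu=2.5)) == pytest.approx(1.0)

    def test_zero_viscosity_rejected(self):
        with pytest.raises(InvalidInputError):
            spec(mu=0.0)

    @given(rho=positive, n=positive, scale=st.floats(min_value=0.5,
                                                     max_value=4.0))
    def test_linear_in_density(self, rho, n, scale):
        base = reynolds(spec(n=n, rho=rho))
        assert reynolds(spec(n=n, rho=scale * rho)) \
            == pytest.approx(scale * base, rel=1e-9)


class TestMixingTime:
    def test_design_point(self):
        # P/V = 10 kW/m^3 in a 0.23 m vessel with a 0.12 m impeller
        s = spec(d_imp=0.12, d_ves=0.23, p=80.0, v=0.008)
        assert mixing_time(s) == pytest.approx(0.128, abs=1e-3)

    def test_cube_root_power_law(self):
        s1 = spec(d_imp=0.12, d_ves=0.23, p=80.0, v=0.008)
        s8 = spec(d_imp=0.12, d_ves=0.23, p=8 * 80.0, v=0.008)
        assert mixing_time(s8) == pytest.approx(mixing_time(s1) / 2, rel=1e-12)

    def test_forced_cancellation(self):
        s = spec(d_imp=1.0, d_ves=1.0, p=5.9 ** 3, v=1.0)
        assert mixing_time(s) == pytest.approx(1.0, rel=1e-12)

    def test_zero_power_rejected(self):
        with pytest.raises(InvalidInputError):
            mixing_time(spec(d_imp=0.12, d_ves=0.23, p=None, v=0.008))


class TestChemostat:
    def test_closed_form(self):
        monod = MonodParams(mu_max=0.5, K_s=0.1, yield_Yxs=0.4,
                            substrate_feed=8.0)
        s, x = chemostat_steady_state(monod, 0.25)
        assert s == pytest.approx(0.1)
        assert x == pytest.approx(3.16)

    def test_washout(self):
        monod = MonodParams()
        s, x = chemostat_steady_state(monod, monod.mu_max)
        assert (s, x) == (monod.substrate_feed, 0.0)

    def test_zero_net_substrate(self):
        # S* = S0 exactly at the dilution rate that consumes nothing
        monod = MonodParams(mu_max=0.5, K_s=0.1, substrate_feed=0.1)
        d = monod.mu_max * monod.substrate_feed \
            / (monod.K_s + monod.substrate_feed)
        s, x = chemostat_steady_state(monod, d)
        assert s == pytest.approx(monod.substrate_feed)
        assert x == pytest.approx(0.0, abs=1e-12)

    def test_negative_dilution_rejected(self):
        with pytest.raises(InvalidInputError):
            chemostat_steady_state(MonodParams(), -0.1)

    def test_matches_ode_integration(self):
        """Closed form equals the long-time limit of the dynamic balances."""
        monod = MonodParams(mu_max=0.5, K_s=0.1, yield_Yxs=0.4,
                            substrate_feed=8.0)
        d = 0.25
        perf = PerfusionSpec(bleed_fraction=1.0, recycle_condensation=1.0,
                             residence_time=1.0 / d)
        sol = solve_ivp(perfusion_rhs, (0.0, 2000.0), [0.1, 8.0],
                        args=(monod, perf), rtol=1e-10, atol=1e-12)
        x_ode, s_ode = sol.y[0][-1], sol.y[1][-1]
        s_cf, x_cf = chemostat_steady_state(monod, d)
        assert x_ode == pytest.approx(x_cf, rel=1e-6)
        assert s_ode == pytest.approx(s_cf, rel=1e-6)


class TestPerfusion:
    def test_reduces_to_chemostat(self):
        monod = MonodParams(maintenance=0.0)
        perf = PerfusionSpec(bleed_fraction=1.0, recycle_condensation=1.0,
                             residence_time=4.0)
        ss = perfusion_steady_state(monod, perf)
        s_cf, x_cf = chemostat_steady_state(monod, 1.0 / 4.0)
        assert ss.substrate_conc == pytest.approx(s_cf)
        assert ss.biomass_conc == pytest.approx(x_cf)

    def test_production_increases_with_bleed(self, baseline):
        """More bleed at fixed residence time lifts the harvest rate (the
        maintenance-burden share of substrate falls as turnover rises)."""
        rates = []
        for b in (0.1, 0.2, 0.3, 0.4):
            perf = dataclasses.replace(baseline.perfusion, bleed_fraction=b)
            rates.append(perfusion_steady_state(baseline.monod,
                                                perf).production_rate)
        assert all(r2 > r1 for r1, r2 in zip(rates, rates[1:]))

    def test_zero_bleed_rejected(self):
        with pytest.raises(NonConvergenceError):
            perfusion_steady_state(MonodParams(),
                                   PerfusionSpec(bleed_fraction=0.0))

    @given(bleed=st.floats(min_value=0.05, max_value=1.0),
           kappa=st.floats(min_value=1.0, max_value=3.0),
           tau=st.floats(min_value=2.0, max_value=50.0),
           ms=st.floats(min_value=0.0, max_value=0.2))
    def test_bounds_and_mass_conservation(self, bleed, kappa, tau, ms):
        monod = MonodParams(maintenance=ms)
        perf = PerfusionSpec(bleed_fraction=bleed,
                             recycle_condensation=kappa, residence_time=tau)
        ss = perfusion_steady_state(monod, perf)
        assert ss.biomass_conc >= 0
        assert 0 <= ss.substrate_conc <= monod.substrate_feed
        if not ss.washout:
            # substrate in = substrate out + growth/Y + maintenance
            fin = perf.working_volume / tau
            consumed = (ss.dilution_rate * ss.biomass_conc
                        / monod.yield_Yxs
                        + ms * ss.biomass_conc) * perf.working_volume
            inflow = fin * monod.substrate_feed
            outflow = fin * ss.substrate_conc
            assert inflow == pytest.approx(outflow + consumed, rel=1e-9)

    def test_matches_ode_oracle(self, baseline):
        ss = perfusion_steady_state(baseline.monod, baseline.perfusion)
        sol = solve_ivp(perfusion_rhs, (0.0, 5000.0), [0.5, 8.0],
                        args=(baseline.monod, baseline.perfusion),
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0][-1] == pytest.approx(ss.biomass_conc, rel=1e-6)
        assert sol.y[1][-1] == pytest.approx(ss.substrate_conc, rel=1e-6)
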