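"""Upstream perfusion culture: agitation criteria and Monod steady states.

The upstream stage grows an *E. coli* culture in a stirred perfusion
bioreactor.  Vessel hydrodynamics are summarised by three dimensionless /
empirical criteria (Froude number, impeller Reynolds number, mixing time)
and the biomass balance by Monod growth kinetics, either as a classic
chemostat or with the perfusion stream topology: the culture is pumped
through a cell-retaining ultrafilter, the cell-free permeate leaves, the
concentrated retentate splits into a product bleed (the only stream that
removes cells) and a recycle that returns to the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._units import G_ACCEL
from .errors import InvalidInputError, NonConvergenceError


@dataclass
class MixingSpec:
    """Geometry, fluid and agitation state of a stirred vessel.

    rotation_rate is in Hz (see :func:`mrnaplant._units.rpm_to_hz` for bench
    rpm values); lengths in m, density kg/m^3, viscosity Pa*s, power W,
    volume m^3.
    """

    rotation_rate: float
    impeller_diameter: float
    vessel_diameter: float
    fluid_density: float = 1000.0
    fluid_viscosity: float = 1e-3
    agitation_power: float | None = None
    fluid_volume: float | None = None

    def __post_init__(self) -> None:
        if self.rotation_rate < 0:
            raise InvalidInputError("rotation_rate must be >= 0")
        for name in ("impeller_diameter", "vessel_diameter", "fluid_density",
                     "fluid_viscosity"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.impeller_diameter > self.vessel_diameter:
            raise InvalidInputError(
                "impeller_diameter must not exceed vessel_diameter")
        for name in ("agitation_power", "fluid_volume"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidInputError(f"{name} must be > 0 when given")


@dataclass
class MonodParams:
    """Monod growth kinetics on glucose.

    ``mu_max`` (1/h) and ``K_s`` (g/L) are configuration defaults typical of
    *E. coli* on glucose, not measured values; the biomass yield on glucose
    is 0.4 g/g.  ``maintenance`` is the Pirt maintenance coefficient
    (g substrate per g biomass per h, default 0 = pure Monod).
    """

    mu_max: float = 0.5
    K_s: float = 0.1
    yield_Yxs: float = 0.4
    substrate_feed: float = 8.0
    maintenance: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise InvalidInputError("mu_max must be > 0")
        if self.K_s <= 0:
            raise InvalidInputError("K_s must be > 0")
        if not 0 < self.yield_Yxs <= 1:
            raise InvalidInputError("yield_Yxs must be in (0, 1]")
        if self.substrate_feed < 0:
            raise InvalidInputError("substrate_feed must be >= 0")
        if self.maintenance < 0:
            raise InvalidInputError("maintenance must be >= 0")


@dataclass
class PerfusionSpec:
    """Perfusion-stage stream topology parameters.

    working_volume L; perfusion_flux L m^-2 h^-1; membrane_area m^2;
    membrane_pore_diameter um; bleed_fraction = bleed flow / feed flow;
    recycle_condensation = retentate cell concentration factor (>= 1);
    residence_time = working_volume / feed flow, h.
    """

    working_volume: float = 1000.0
    perfusion_flux: float = 5.0
    membrane_area: float = 40.0
    membrane_pore_diameter: float = 0.65
    bleed_fraction: float = 0.2
    recycle_condensation: float = 2.0
    residence_time: float = 20.0

    def __post_init__(self) -> None:
        if not 0 <= self.bleed_fraction <= 1:
            raise InvalidInputError("bleed_fraction must be in [0, 1]")
        if self.recycle_condensation < 1:
            raise InvalidInputError("recycle_condensation must be >= 1")
        for name in ("working_volume", "perfusion_flux", "membrane_area",
                     "membrane_pore_diameter", "residence_time"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


def froude(spec: MixingSpec) -> float:
    """Froude number Fr = N^2 D / g on the vessel diameter.

    The design criterion for uniform mixing is Fr < 0.1; callers emit a
    warning (see the report stage) when the criterion is violated.
    """
    return spec.rotation_rate ** 2 * spec.vessel_diameter / G_ACCEL


def reynolds(spec: MixingSpec, diameter: str = "impeller") -> float:
    """Impeller Reynolds number Re = rho N D^2 / mu.

    ``diameter`` selects which diameter enters the power law: "impeller"
    (default, the usual stirred-tank convention) or "vessel".
    """
    if diameter == "impeller":
        d = spec.impeller_diameter
    elif diameter == "vessel":
        d = spec.vessel_diameter
    else:
        raise InvalidInputError("diameter must be 'impeller' or 'vessel'")
    if spec.fluid_viscosity <= 0:
        raise InvalidInputError("fluid_viscosity must be > 0")
    return spec.fluid_density * spec.rotation_rate * d ** 2 / spec.fluid_viscosity


def mixing_time(spec: MixingSpec) -> float:
    """Homogenisation time Theta_m (s) of a stirred vessel.

    Theta_m = 5.9 (P/V)^(-1/3) (d_R/D_R)^(-1/3) D_R^(2/3) with P/V in W/m^3
    and diameters in m.
    """
    if spec.agitation_power is None or spec.fluid_volume is None:
        raise InvalidInputError("agitation_power and fluid_volume are required")
    if spec.agitation_power <= 0:
        raise InvalidInputError("agitation_power must be > 0")
    pv = spec.agitation_power / spec.fluid_volume
    ratio = spec.impeller_diameter / spec.vessel_diameter
    return 5.9 * pv ** (-1.0 / 3.0) * ratio ** (-1.0 / 3.0) \
        * spec.vessel_diameter ** (2.0 / 3.0)


def chemostat_steady_state(monod: MonodParams,
                           dilution_rate: float) -> tuple[float, float]:
    """Closed-form chemostat steady state (pure Monod, no maintenance).

    Returns ``(residual substrate g/L, biomass g/L)``:
    S* = K_s D / (mu_max - D), X* = Y_xs (S0 - S*).  At or beyond washout
    (D >= mu_max, or S* >= S0) returns (S0, 0).
    """
    if dilution_rate < 0:
        raise InvalidInputError("dilution_rate must be >= 0")
    s0 = monod.substrate_feed
    if dilution_rate >= monod.mu_max:
        return s0, 0.0
    s_star = monod.K_s * dilution_rate / (monod.mu_max - dilution_rate)
    if s_star >= s0:
        return s0, 0.0
    return s_star, monod.yield_Yxs * (s0 - s_star)


@dataclass
class PerfusionSteadyState:
    biomass_conc: float        # g/L in the vessel
    substrate_conc: float      # g/L residual
    production_rate: float     # g biomass / h through the bleed
    dilution_rate: float       # effective cell-specific removal rate, 1/h
    feed_flow: float           # L/h
    washout: bool


def perfusion_steady_state(monod: MonodParams,
                           perf: PerfusionSpec) -> PerfusionSteadyState:
    """Steady state of the perfusion loop.

    Stream closure: feed F_in = V / tau; bleed F_b = beta F_in removing cells
    at the retentate concentration kappa * X; permeate (1 - beta) F_in is
    cell free; substrate is unretained, so it leaves at the vessel
    concentration in both outlets.  Balances::

        cells:      mu(S*) X = (beta kappa / tau) X
        substrate:  (S0 - S*) / tau = mu(S*) X / Y + m_s X

    with the Pirt maintenance term m_s.  The production rate is the bleed
    cell flux F_b kappa X = mu(S*) X V.  With kappa = 1, beta = 1 and
    m_s = 0 this reduces exactly to the chemostat closed form.
    """
    if perf.bleed_fraction <= 0:
        raise NonConvergenceError(
            "bleed_fraction = 0: cells are never removed and the culture "
            "accumulates without bound; no steady state exists")
    feed_flow = perf.working_volume / perf.residence_time
    d_eff = perf.bleed_fraction * perf.recycle_condensation / perf.residence_time
    s0 = monod.substrate_feed
    if d_eff >= monod.mu_max:
        return PerfusionSteadyState(0.0, s0, 0.0, d_eff, feed_flow, True)
    s_star = monod.K_s * d_eff / (monod.mu_max - d_eff)
    if s_star >= s0:
        return PerfusionSteadyState(0.0, s0, 0.0, d_eff, feed_flow, True)
    # substrate balance: (S0-S*)/tau = X (d_eff/Y + m_s)
    x_star = (s0 - s_star) / perf.residence_time \
        / (d_eff / monod.yield_Yxs + monod.maintenance)
    production = d_eff * x_star * perf.working_volume
    return PerfusionSteadyState(x_star, s_star, production, d_eff,
                                feed_flow, False)


def perfusion_rhs(t, y, monod: MonodParams, perf: PerfusionSpec):
    """ODE right-hand side of the perfusion balances (for oracle use)."""
    x, s = y
    s = max(s, 0.0)
    mu = monod.mu_max * s / (monod.K_s + s)
    d_eff = perf.bleed_fraction * perf.recycle_condensation / perf.residence_time
    dx = (mu - d_eff) * x
    ds = (monod.substrate_feed - s) / perf.residence_time \
        - (mu / monod.yield_Yxs + monod.maintenance) * x
    return [dx, ds]
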