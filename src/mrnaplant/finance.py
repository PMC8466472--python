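"""Discounted-cash-flow economics and Monte-Carlo uncertainty.

The plant is equity financed over a 30-year lifetime whose first 3 years
are construction; revenue starts in year 4.  Depreciation follows the
half-year 5-year MACRS schedule on the fixed capital investment.  The
minimum selling price per dose (MSPD) is the price at which the net present
value of the whole venture is exactly zero:

    NPV = -C0 + sum_n C_n / (1 + r)^n,
    C_n = (R_n - COM_d - d_n)(1 - t) + d_n.

Uncertainty propagates triangular priors (material unit prices -10 %/+30 %,
discount and tax rates +/-40 %) through the full cost chain, re-solving the
MSPD per draw; the sensitivity is summarised by one-at-a-time tornado
swings and a shifted log-normal density fitted to the sample histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import BracketingError, InvalidInputError, NonConvergenceError

MACRS_5YR = (0.20, 0.32, 0.192, 0.1152, 0.1152, 0.0576)


@dataclass
class FinanceParams:
    """Financing assumptions of the venture."""

    lifetime_years: int = 30
    construction_years: int = 3
    discount_rate: float = 0.10
    tax_rate: float = 0.21
    dose_mass_ug: float = 30.0
    annual_api_mass_g: float = 8000.0
    capital_phasing: tuple[float, ...] | None = None  # default: even split
    working_capital_recovered_at_end: bool = True
    operators: int = 5
    operator_cost: float = 190_476.0          # EUR per operator-year
    utilities_annual: float = 200_000.0       # EUR/yr beyond the cleanroom

    def __post_init__(self) -> None:
        if not 0 <= self.tax_rate < 1:
            raise InvalidInputError("tax_rate must be in [0, 1)")
        if self.discount_rate <= -1:
            raise InvalidInputError("discount_rate must be > -1")
        if self.construction_years >= self.lifetime_years:
            raise InvalidInputError(
                "construction_years must be < lifetime_years")
        if self.capital_phasing is None:
            n = self.construction_years
            self.capital_phasing = tuple([1.0 / n] * n)
        if abs(sum(self.capital_phasing) - 1.0) > 1e-9:
            raise InvalidInputError("capital_phasing must sum to 1")
        if len(self.capital_phasing) != self.construction_years:
            raise InvalidInputError(
                "capital_phasing length must equal construction_years")

    @property
    def doses_per_year(self) -> float:
        return round(self.annual_api_mass_g * 1e6 / self.dose_mass_ug)

    @property
    def labor_cost(self) -> float:
        return self.operators * self.operator_cost


@dataclass
class TriangularParam:
    """Triangular prior on a scenario parameter.

    ``target`` is either ``("material", <name>)`` for a material unit price
    or ``("finance", <field>)`` for a finance rate.  The distribution is
    resolved as baseline x (1 + low_conversion / high_conversion) with the
    mode at the baseline.
    """

    name: str
    target: tuple[str, str]
    baseline: float
    low_conversion: float = -0.10
    high_conversion: float = 0.30

    def __post_init__(self) -> None:
        if self.low_conversion > 0 or self.high_conversion < 0:
            raise InvalidInputError(
                f"{self.name}: conversions must bracket the baseline")

    @property
    def resolved(self) -> tuple[float, float, float]:
        lo = self.baseline * (1.0 + self.low_conversion)
        hi = self.baseline * (1.0 + self.high_conversion)
        if not lo <= self.baseline <= hi:
            raise InvalidInputError(f"{self.name}: min <= mode <= max violated")
        return lo, self.baseline, hi


@dataclass
class MonteCarloResult:
    samples: np.ndarray
    n_iterations: int
    seed: int
    baseline: float
    median: float
    percentiles: dict[int, float]
    histogram: tuple[np.ndarray, np.ndarray]
    tornado: list[tuple[str, float, float]]   # (name, low MSPD, high MSPD)
    density_fit: dict[str, float] | None = None


# ---------------------------------------------------------------------------

def macrs_schedule(fci: float) -> list[float]:
    """Per-year depreciation (EUR) under half-year 5-year MACRS; sums to FCI."""
    if fci < 0:
        raise InvalidInputError("FCI must be >= 0")
    return [fci * f for f in MACRS_5YR]


def annual_cash_flow(revenue: float, com_d: float, depreciation: float,
                     tax_rate: float) -> float:
    """C_n = (R_n - COM_d - d_n)(1 - t) + d_n."""
    if not 0 <= tax_rate < 1:
        raise InvalidInputError("tax_rate must be in [0, 1)")
    return (revenue - com_d - depreciation) * (1.0 - tax_rate) + depreciation


def npv(flows: np.ndarray, rate: float) -> float:
    """Net present value of per-year flows indexed from year 0."""
    if rate <= -1:
        raise InvalidInputError("rate must be > -1")
    flows = np.asarray(flows, dtype=float)
    years = np.arange(len(flows))
    return float(np.sum(flows / (1.0 + rate) ** years))


def venture_flows(price_per_dose: float, com_d_annual: float, fci: float,
                  tci: float, fin: FinanceParams) -> np.ndarray:
    """Full per-year cash-flow vector of the venture (year 0..lifetime).

    Construction years carry the phased TCI outflow; operating years earn
    the after-tax flow of :func:`annual_cash_flow` with MACRS depreciation
    starting the first operating year; working capital returns in the final
    year when configured.
    """
    flows = np.zeros(fin.lifetime_years + 1)
    for i, frac in enumerate(fin.capital_phasing, start=1):
        flows[i] -= tci * frac
    revenue = price_per_dose * fin.doses_per_year
    dep = macrs_schedule(fci)
    first_op = fin.construction_years + 1
    for year in range(first_op, fin.lifetime_years + 1):
        d_n = dep[year - first_op] if year - first_op < len(dep) else 0.0
        flows[year] += annual_cash_flow(revenue, com_d_annual, d_n,
                                        fin.tax_rate)
    if fin.working_capital_recovered_at_end:
        flows[fin.lifetime_years] += tci - fci
    return flows


def venture_npv(price_per_dose: float, com_d_annual: float, fci: float,
                tci: float, fin: FinanceParams) -> float:
    return npv(venture_flows(price_per_dose, com_d_annual, fci, tci, fin),
               fin.discount_rate)


def solve_mspd(com_d_annual: float, fci: float, tci: float,
               fin: FinanceParams, bracket: tuple[float, float] = (0.01, 100.0),
               tol: float = 1.0) -> float:
    """Bisect the dose price until |NPV| < ``tol`` euros.

    NPV is strictly increasing in price (revenue enters every operating
    year with positive after-tax weight), so bisection converges; a bracket
    without a sign change raises :class:`BracketingError`.
    """
    lo, hi = bracket
    f_lo = venture_npv(lo, com_d_annual, fci, tci, fin)
    f_hi = venture_npv(hi, com_d_annual, fci, tci, fin)
    if f_lo >= 0:
        return lo  # degenerate scenario: even the floor price pays back
    if f_hi < 0:
        raise BracketingError(
            f"MSPD above the bracket ceiling {hi} EUR/dose (NPV {f_hi:.3g})")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = venture_npv(mid, com_d_annual, fci, tci, fin)
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise NonConvergenceError("MSPD bisection did not reach tolerance")


def sample_triangular(param: TriangularParam,
                      rng: np.random.Generator) -> float:
    """One inverse-CDF triangular draw within [min, max]."""
    lo, mode, hi = param.resolved
    if lo == hi:
        return mode
    return float(rng.triangular(lo, mode, hi))


# ---------------------------------------------------------------------------
# full-chain rebuild helpers: the scenario module wires these to real
# PlantScenario objects; finance_mc only needs a callable contract.

def monte_carlo_mspd(rebuild, priors: list[TriangularParam], n: int,
                     seed: int,
                     fit_density: bool = False) -> MonteCarloResult:
    """Monte-Carlo MSPD distribution.

    ``rebuild(overrides)`` maps a dict ``{(kind, key): value}`` of perturbed
    parameters to a solved MSPD (EUR/dose); it is called once per iteration
    with every prior drawn independently.  Deterministic for a fixed seed.
    """
    if n < 100:
        raise InvalidInputError("n must be >= 100")
    rng = np.random.default_rng(seed)
    baseline = rebuild({})
    samples = np.empty(n)
    for i in range(n):
        overrides = {p.target: sample_triangular(p, rng) for p in priors}
        try:
            samples[i] = rebuild(overrides)
        except BracketingError as exc:
            raise BracketingError(f"iteration {i}: {exc}") from exc
    pct_levels = (1, 5, 25, 50, 75, 95, 99)
    pct = {p: float(np.percentile(samples, p)) for p in pct_levels}
    hist = np.histogram(samples, bins=50, density=True)
    swings = tornado(rebuild, priors)
    result = MonteCarloResult(
        samples=samples, n_iterations=n, seed=seed, baseline=baseline,
        median=float(np.median(samples)), percentiles=pct,
        histogram=hist, tornado=swings)
    if fit_density:
        result.density_fit = fit_mspd_density(samples)
    return result


def tornado(rebuild, priors: list[TriangularParam]
            ) -> list[tuple[str, float, float]]:
    """One-at-a-time (low, high) MSPD per prior, sorted by swing size."""
    out = []
    for p in priors:
        lo, _, hi = p.resolved
        mspd_lo = rebuild({p.target: lo})
        mspd_hi = rebuild({p.target: hi})
        out.append((p.name, mspd_lo, mspd_hi))
    out.sort(key=lambda t: abs(t[2] - t[1]), reverse=True)
    return out


def _density_form(x, a, b, c, m):
    return a + b / (c * np.sqrt(2.0 * np.pi) * x) \
        * np.exp(-np.log(x / m) ** 2 / (2.0 * c ** 2))


def fit_mspd_density(samples: np.ndarray) -> dict[str, float]:
    """Fit y = a + b/(c sqrt(2 pi) x) exp(-ln(x/m)^2 / (2 c^2)) to the
    normalised sample histogram (nonlinear least squares).

    Returns the parameters plus an R^2 goodness of fit.  Degenerate
    (constant) samples raise :class:`NonConvergenceError`.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 1000:
        raise InvalidInputError("need >= 1000 samples for a stable fit")
    if np.ptp(samples) <= 0:
        raise NonConvergenceError(
            "degenerate histogram: all samples identical")
    density, edges = np.histogram(samples, bins=50, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    logs = np.log(samples[samples > 0])
    p0 = (0.0, 1.0, max(float(np.std(logs)), 1e-3),
          float(np.exp(np.median(logs))))
    try:
        popt, _ = curve_fit(_density_form, centers, density, p0=p0,
                            maxfev=20000)
    except RuntimeError as exc:
        raise NonConvergenceError(
            f"density fit did not converge: {exc}") from exc
    fitted = _density_form(centers, *popt)
    ss_res = float(np.sum((density - fitted) ** 2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    a, b, c, m = (float(v) for v in popt)
    return {"offset": a, "amplitude": b, "width": c, "scale": m,
            "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")}
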