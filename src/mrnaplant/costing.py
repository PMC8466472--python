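"""Equipment and materials costing for the plant scenario.

Purchase costs scale from reference quotes by the power-law (Lang-exponent)
rule Cp = Cp0 (X/X0)^n and are escalated between years with a
Chemical-Engineering-Plant-Cost-Index (CEPCI) style series.  Capital
investment follows percentage-of-delivered-equipment factoring for a
solid-fluid processing plant; the cleanroom life-cycle cost comes from a
published empirical regression; the annual cost of manufacture (no
depreciation) is

    COM_d = 0.18 FCI + 2.73 C_L + 1.23 (C_U + C_W + C_R)

Stage-wise resource shares group equipment or material cost by flowsheet
stage (fermentation, cell_lysis, linearization, ivt, formulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError, LookupError_

STAGE_GROUPS = ("fermentation", "cell_lysis", "linearization", "ivt",
                "formulation")


@dataclass
class EquipmentItem:
    """One row of the equipment table.

    Sized items carry a reference (cost, size, year) and a Lang exponent;
    fixed-price items (pumps, skid chromatography units...) have no sizes
    and pass through :func:`lang_scale` unchanged.  Sizes carry their unit
    ("m3" or "m2") and must match between reference and simulated size.
    """

    id: str
    description: str
    ref_cost: float
    ref_year: int
    stage_group: str
    ref_size: float | None = None
    sim_size: float | None = None
    size_unit: str | None = None
    lang_exponent: float | None = None

    def __post_init__(self) -> None:
        if self.ref_cost < 0:
            raise InvalidInputError(f"{self.id}: ref_cost must be >= 0")
        if self.stage_group not in STAGE_GROUPS:
            raise InvalidInputError(
                f"{self.id}: unknown stage_group {self.stage_group!r}")
        sized = self.ref_size is not None or self.sim_size is not None
        if sized:
            if self.ref_size is None or self.sim_size is None:
                raise InvalidInputError(
                    f"{self.id}: both ref_size and sim_size required for a "
                    "sized item")
            if self.ref_size <= 0 or self.sim_size <= 0:
                raise InvalidInputError(f"{self.id}: sizes must be > 0")
            if self.lang_exponent is None:
                raise InvalidInputError(
                    f"{self.id}: sized item is missing its Lang exponent")
            if not 0 <= self.lang_exponent <= 1.2:
                raise InvalidInputError(
                    f"{self.id}: lang_exponent must be in [0, 1.2]")
            if self.size_unit not in ("m3", "m2"):
                raise InvalidInputError(
                    f"{self.id}: size_unit must be 'm3' or 'm2'")

    @property
    def is_sized(self) -> bool:
        return self.ref_size is not None


@dataclass
class CostIndexSeries:
    """Year -> plant cost index value."""

    name: str
    values: dict[int, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise InvalidInputError("cost index values must be > 0")

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[int(year)]
        except KeyError:
            raise LookupError_(
                f"cost index {self.name!r} has no value for year {year}")


@dataclass
class MaterialItem:
    """One row of the raw-materials table.

    ``annual_quantity`` already reflects any replacement rule (e.g. resin
    replaced every 100 cycles); ``replacement_cycles`` documents that rule.
    """

    name: str
    unit_price: float
    price_unit: str
    annual_quantity: float
    quantity_unit: str
    stage_group: str
    replacement_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.unit_price < 0 or self.annual_quantity < 0:
            raise InvalidInputError(
                f"{self.name}: price and quantity must be >= 0")
        if self.stage_group not in STAGE_GROUPS:
            raise InvalidInputError(
                f"{self.name}: unknown stage_group {self.stage_group!r}")
        pu = self.price_unit.split("/")
        qu = self.quantity_unit.split("/")
        if len(pu) == 2 and pu[1] != qu[0]:
            raise InvalidInputError(
                f"{self.name}: price per {pu[1]!r} does not match quantity "
                f"in {qu[0]!r}")

    @property
    def annual_cost(self) -> float:
        return self.unit_price * self.annual_quantity


@dataclass
class CapitalFactors:
    """Percent-of-delivered-equipment factors (solid-fluid plant)."""

    direct: dict[str, float] = field(default_factory=lambda: {
        "purchased_equipment": 100.0,
        "installation": 39.0,
        "instrumentation": 26.0,
        "piping": 31.0,
        "electrical": 10.0,
        "buildings": 29.0,
        "yard_improvements": 12.0,
        "service_facilities": 55.0,
    })
    indirect: dict[str, float] = field(default_factory=lambda: {
        "engineering_supervision": 32.0,
        "construction_expenses": 34.0,
        "legal_expenses": 4.0,
        "contractor_fee": 19.0,
        "contingency": 37.0,
    })
    working_capital_fraction: float = 0.15

    def __post_init__(self) -> None:
        if any(v < 0 for v in {**self.direct, **self.indirect}.values()):
            raise InvalidInputError("capital factors must be >= 0")
        if not 0 <= self.working_capital_fraction < 1:
            raise InvalidInputError(
                "working_capital_fraction must be in [0, 1)")

    @property
    def fci_multiplier(self) -> float:
        return (sum(self.direct.values()) + sum(self.indirect.values())) / 100.0


@dataclass
class CleanroomSpec:
    """Inputs of the cleanroom life-cycle-cost regression.

    CL, AAV, RAV, THF and TC are defined by the source study but carry no
    coefficient in the published equation; they are stored for completeness
    and unused.
    """

    CA: float = 500.0          # cleanroom area, m^2
    MAV: float = 20.0          # make-up air volume, m^3/s
    EAV: float = 10.0          # exhaust air volume, m^3/s
    TAV1: float = 1.0          # air-ventilation type indicator (FFU)
    TAR: float = 1.0           # air-return type indicator (raised floor)
    AFC: float = 0.3           # average filter coverage fraction
    CL: float | None = None
    AAV: float | None = None
    RAV: float | None = None
    THF: float | None = None
    TC: float | None = None
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "intercept": -1_645_051.0,
        "CA": 5156.6,
        "MAV": 68.8,
        "EAV": 34.0,
        "TAV1": 514_211.0,
        "TAR": -742_442.0,
        "AFC": 2_996_627.0,
    })

    def __post_init__(self) -> None:
        if self.CA <= 0:
            raise InvalidInputError("CA must be > 0")
        if not 0 <= self.AFC <= 1:
            raise InvalidInputError("AFC must be in [0, 1]")


@dataclass
class CostBreakdown:
    """Ledger of the capital and operating cost components (EUR)."""

    delivered_equipment: float = 0.0
    FCI: float = 0.0
    TCI: float = 0.0
    C_L: float = 0.0
    C_U: float = 0.0
    C_W: float = 0.0
    C_R: float = 0.0
    COM_d: float = 0.0
    equipment_by_group: dict[str, float] = field(default_factory=dict)
    materials_by_group: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------

def lang_scale(item: EquipmentItem) -> float:
    """Reference-year purchase cost at the simulated size:
    Cp = Cp0 (X / X0)^n; fixed-price items pass through."""
    if not item.is_sized:
        return item.ref_cost
    return item.ref_cost * (item.sim_size / item.ref_size) ** item.lang_exponent


def cepci_adjust(cost: float, from_year: int, to_year: int,
                 index: CostIndexSeries) -> float:
    """Escalate ``cost`` from ``from_year`` to ``to_year`` euros."""
    if from_year == to_year:
        return cost
    return cost * index[to_year] / index[from_year]


def equipment_cost(item: EquipmentItem, index: CostIndexSeries,
                   to_year: int = 2021) -> float:
    """Lang-scaled then inflation-adjusted cost in ``to_year`` euros."""
    return cepci_adjust(lang_scale(item), item.ref_year, to_year, index)


def capital_from_equipment(delivered: float,
                           factors: CapitalFactors) -> tuple[float, float]:
    """(FCI, TCI) from the delivered-equipment cost.

    FCI = delivered x (sum of direct + indirect percentages)/100;
    working capital is a fraction of TCI, so TCI = FCI / (1 - wc_fraction).
    """
    if delivered < 0:
        raise InvalidInputError("delivered must be >= 0")
    fci = delivered * factors.fci_multiplier
    tci = fci / (1.0 - factors.working_capital_fraction)
    return fci, tci


def cleanroom_lcc(spec: CleanroomSpec, floor_at_zero: bool = False) -> float:
    """Cleanroom life-cycle cost (EUR) from the empirical regression.

    The linear model can go negative for small areas; that is a documented
    behaviour of the published fit, optionally floored at 0.
    """
    c = spec.coefficients
    lcc = (c["intercept"] + c["CA"] * spec.CA + c["MAV"] * spec.MAV
           + c["EAV"] * spec.EAV + c["TAV1"] * spec.TAV1
           + c["TAR"] * spec.TAR + c["AFC"] * spec.AFC)
    return max(lcc, 0.0) if floor_at_zero else lcc


def bill_of_materials(items: list[MaterialItem]) -> tuple[float, dict, dict]:
    """(C_R EUR/yr, per-item costs, per-group subtotals); totals are always
    recomputed as quantity x unit price."""
    per_item = {it.name: it.annual_cost for it in items}
    per_group = dict.fromkeys(STAGE_GROUPS, 0.0)
    for it in items:
        per_group[it.stage_group] += it.annual_cost
    return sum(per_item.values()), per_item, per_group


def com_d(breakdown: CostBreakdown) -> float:
    """Annual cost of manufacture without depreciation (EUR/yr)."""
    return (0.18 * breakdown.FCI + 2.73 * breakdown.C_L
            + 1.23 * (breakdown.C_U + breakdown.C_W + breakdown.C_R))


def group_shares(costs_by_group: dict[str, float]
                 ) -> tuple[dict[str, int], dict[str, float]]:
    """Stage shares of a cost dict: (rounded integer %, raw fractions)."""
    total = sum(costs_by_group.values())
    if total <= 0:
        raise InvalidInputError("grand total must be > 0 for shares")
    fractions = {g: v / total for g, v in costs_by_group.items()}
    rounded = {g: int(round(100.0 * f)) for g, f in fractions.items()}
    return rounded, fractions


def equipment_group_costs(items: list[EquipmentItem],
                          index: CostIndexSeries,
                          to_year: int = 2021) -> dict[str, float]:
    out = dict.fromkeys(STAGE_GROUPS, 0.0)
    for it in items:
        out[it.stage_group] += equipment_cost(it, index, to_year)
    return out
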