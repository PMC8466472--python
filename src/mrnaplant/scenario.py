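"""Plant scenario data model, file I/O and synthetic-scenario generation.

A :class:`PlantScenario` is the single serializable object the pipeline
consumes: equipment and material tables, capital factors, cleanroom and
finance parameters, uncertainty priors, and the process parameter blocks
(mixing, Monod, perfusion, chromatography columns, IVT kinetics, LNP
shell).  Scenarios round-trip losslessly through a directory bundle of one
YAML file plus two delimited tables (diff-able, line-oriented).

The synthetic generator emits randomized but schema-valid scenarios with
the same statistical shape as the baseline fixture (log-uniform prices and
sizes, Lang exponents in [0.2, 0.8], -10 %/+30 % material priors, +/-40 %
rate priors) so every stage is property-testable on fresh inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixture
from .chromatography import ColumnSpec
from .costing import (STAGE_GROUPS, CapitalFactors, CleanroomSpec,
                      CostBreakdown, CostIndexSeries, EquipmentItem,
                      MaterialItem, bill_of_materials, capital_from_equipment,
                      cleanroom_lcc, com_d, equipment_cost,
                      equipment_group_costs)
from .errors import ScenarioValidationError
from .finance import FinanceParams, TriangularParam, solve_mspd
from .ivt import IVTParams
from .lnp import ShellSpec
from .perfusion import MixingSpec, MonodParams, PerfusionSpec

EQUIPMENT_COLUMNS = ["id", "description", "ref_cost", "ref_year",
                     "stage_group", "ref_size", "sim_size", "size_unit",
                     "lang_exponent"]
MATERIAL_COLUMNS = ["name", "unit_price", "price_unit", "annual_quantity",
                    "quantity_unit", "stage_group", "replacement_cycles"]


def _baseline_columns() -> dict[str, ColumnSpec]:
    """Chromatography design-table rows of the baseline plant."""
    return {
        "HIC-201": ColumnSpec(linear_velocity=None, bed_height=None,
                              kozeny_constant=150.0, porosity=0.3,
                              particle_diameter=30.0, n_columns=4,
                              column_height=42.8, column_diameter=21.4,
                              retention_time=20.0),
        "AEX-201": ColumnSpec(pressure_drop=0.5, linear_velocity=0.004,
                              bed_height=9.0, kozeny_constant=150.0,
                              porosity=0.4, particle_diameter=0.8,
                              n_columns=4, column_height=12.8,
                              column_diameter=6.4, retention_time=20.0),
        "SEC-201": ColumnSpec(pressure_drop=0.003, linear_velocity=0.007,
                              bed_height=30.0, kozeny_constant=180.0,
                              porosity=0.3, particle_diameter=47.0,
                              n_columns=4, column_height=42.8,
                              column_diameter=21.4, retention_time=20.0),
        "AEX-301": ColumnSpec(pressure_drop=0.1, linear_velocity=0.002,
                              bed_height=5.0, kozeny_constant=150.0,
                              porosity=0.4, particle_diameter=0.8,
                              n_columns=4, column_height=7.2,
                              column_diameter=3.6, retention_time=5.0),
        "AFC-301": ColumnSpec(kozeny_constant=150.0, porosity=0.3,
                              n_columns=4, column_height=23.4,
                              column_diameter=11.7, retention_time=20.0),
        "HPLC-301": ColumnSpec(pressure_drop=0.5, linear_velocity=0.003,
                               bed_height=25.0, kozeny_constant=150.0,
                               porosity=0.3, particle_diameter=2.1,
                               n_columns=4, column_height=35.6,
                               column_diameter=17.8, retention_time=20.0),
    }


@dataclass
class PlantScenario:
    """Complete description of one plant configuration."""

    name: str
    equipment: list[EquipmentItem]
    materials: list[MaterialItem]
    capital_factors: CapitalFactors = field(default_factory=CapitalFactors)
    cleanroom: CleanroomSpec = field(default_factory=CleanroomSpec)
    finance: FinanceParams = field(default_factory=FinanceParams)
    priors: list[TriangularParam] = field(default_factory=list)
    mixing: MixingSpec | None = None
    monod: MonodParams | None = None
    perfusion: PerfusionSpec | None = None
    columns: dict[str, ColumnSpec] = field(default_factory=dict)
    ivt_params: IVTParams | None = None
    shell: ShellSpec | None = None
    cost_index: str = "table_consistent"
    cost_year: int = 2021
    cycles_per_year: int = 11
    process_flow_l_h: float = 10.0

    def __post_init__(self) -> None:
        if not self.equipment:
            raise ScenarioValidationError("scenario has no equipment items")
        if not self.materials:
            raise ScenarioValidationError("scenario has no material items")
        if self.cost_index not in fixture.COST_INDEX_SERIES:
            raise ScenarioValidationError(
                f"unknown cost index {self.cost_index!r}")
        names = [m.name for m in self.materials]
        if len(set(names)) != len(names):
            raise ScenarioValidationError("duplicate material names")
        for p in self.priors:
            kind, key = p.target
            if kind == "material" and key not in names:
                raise ScenarioValidationError(
                    f"prior {p.name!r} targets unknown material {key!r}")
            if kind == "finance" and not hasattr(self.finance, key):
                raise ScenarioValidationError(
                    f"prior {p.name!r} targets unknown finance field {key!r}")

    @property
    def cost_index_series(self) -> CostIndexSeries:
        return fixture.COST_INDEX_SERIES[self.cost_index]

    # -- canonical serialization ------------------------------------------
    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v)
                        for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "name": self.name,
            "cost_index": self.cost_index,
            "cost_year": self.cost_year,
            "cycles_per_year": self.cycles_per_year,
            "process_flow_l_h": self.process_flow_l_h,
            "capital_factors": clean(self.capital_factors),
            "cleanroom": clean(self.cleanroom),
            "finance": clean(self.finance),
            "priors": [clean(p) for p in self.priors],
            "mixing": clean(self.mixing) if self.mixing else None,
            "monod": clean(self.monod) if self.monod else None,
            "perfusion": clean(self.perfusion) if self.perfusion else None,
            "columns": {k: clean(v) for k, v in self.columns.items()},
            "ivt_params": clean(self.ivt_params) if self.ivt_params else None,
            "shell": clean(self.shell) if self.shell else None,
            "equipment": [clean(e) for e in self.equipment],
            "materials": [clean(m) for m in self.materials],
        }

    def content_hash(self) -> str:
        """SHA-256 over the canonical JSON form (fixture-drift guard)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def baseline_scenario() -> PlantScenario:
    """The packaged reference plant (37 equipment rows, 17 materials)."""
    return PlantScenario(
        name="continuous-mrna-lnp-baseline",
        equipment=fixture.baseline_equipment(),
        materials=fixture.baseline_materials(),
        capital_factors=fixture.baseline_capital_factors(),
        cleanroom=fixture.baseline_cleanroom(),
        finance=fixture.baseline_finance(),
        priors=fixture.baseline_priors(),
        mixing=MixingSpec(rotation_rate=200.0 / 60.0, impeller_diameter=0.12,
                          vessel_diameter=0.23, fluid_density=517.0,
                          fluid_viscosity=1e-3, agitation_power=80.0,
                          fluid_volume=0.008),
        monod=MonodParams(mu_max=0.5, K_s=0.1, yield_Yxs=0.4,
                          substrate_feed=8.0, maintenance=0.05),
        perfusion=PerfusionSpec(),
        columns=_baseline_columns(),
        ivt_params=IVTParams(),
        shell=ShellSpec(),
    )


# ---------------------------------------------------------------------------
# file I/O: directory bundle of scenario.yaml + equipment.csv + materials.csv

def save_scenario(scenario: PlantScenario, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = scenario.to_dict()
    equipment = data.pop("equipment")
    materials = data.pop("materials")
    with open(path / "scenario.yaml", "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    pd.DataFrame(equipment)[EQUIPMENT_COLUMNS].to_csv(
        path / "equipment.csv", index=False)
    pd.DataFrame(materials)[MATERIAL_COLUMNS].to_csv(
        path / "materials.csv", index=False)


def _none_ify(record: dict) -> dict:
    return {k: (None if pd.isna(v) else v) for k, v in record.items()}


def _build(cls, record: dict | None):
    if record is None:
        return None
    return cls(**record)


def load_scenario(path) -> PlantScenario:
    path = Path(path)
    yaml_path = path / "scenario.yaml"
    if not yaml_path.exists():
        raise ScenarioValidationError(f"no scenario.yaml under {path}")
    with open(yaml_path) as fh:
        data = yaml.safe_load(fh)
    try:
        equipment = [
            EquipmentItem(**{**r,
                             "ref_year": int(r["ref_year"]),
                             "lang_exponent": r["lang_exponent"]})
            for r in (_none_ify(rec) for rec in pd.read_csv(
                path / "equipment.csv",
                float_precision="round_trip").to_dict("records"))]
        materials = [
            MaterialItem(**{**r, "replacement_cycles":
                            None if r["replacement_cycles"] is None
                            else int(r["replacement_cycles"])})
            for r in (_none_ify(rec) for rec in pd.read_csv(
                path / "materials.csv",
                float_precision="round_trip").to_dict("records"))]
        finance_rec = dict(data["finance"])
        finance_rec["capital_phasing"] = tuple(finance_rec["capital_phasing"])
        priors = [TriangularParam(**{**p, "target": tuple(p["target"])})
                  for p in data.get("priors", [])]
        columns = {k: ColumnSpec(**v)
                   for k, v in (data.get("columns") or {}).items()}
        return PlantScenario(
            name=data["name"],
            equipment=equipment,
            materials=materials,
            capital_factors=_build(CapitalFactors, data["capital_factors"]),
            cleanroom=_build(CleanroomSpec, data["cleanroom"]),
            finance=FinanceParams(**finance_rec),
            priors=priors,
            mixing=_build(MixingSpec, data.get("mixing")),
            monod=_build(MonodParams, data.get("monod")),
            perfusion=_build(PerfusionSpec, data.get("perfusion")),
            columns=columns,
            ivt_params=_build(IVTParams, data.get("ivt_params")),
            shell=_build(ShellSpec, data.get("shell")),
            cost_index=data.get("cost_index", "table_consistent"),
            cost_year=int(data.get("cost_year", 2021)),
            cycles_per_year=int(data.get("cycles_per_year", 11)),
            process_flow_l_h=float(data.get("process_flow_l_h", 10.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError(f"invalid scenario bundle: {exc}") from exc


# ---------------------------------------------------------------------------
# synthetic scenarios

def generate_scenario(seed: int, n_equipment: int = 12,
                      n_materials: int = 8) -> PlantScenario:
    """Seeded random, schema-valid scenario emulating the fixture's shape."""
    if n_equipment < 1 or n_materials < 1:
        raise ScenarioValidationError("need at least one equipment/material")
    rng = np.random.default_rng(seed)
    years = sorted(fixture.CEPCI_TABLE_CONSISTENT.values)
    equipment = []
    for i in range(n_equipment):
        sized = rng.random() < 0.7
        group = STAGE_GROUPS[rng.integers(len(STAGE_GROUPS))]
        ref_cost = float(10 ** rng.uniform(2.5, 6.0))
        year = int(rng.choice(years))
        if sized:
            ref_size = float(10 ** rng.uniform(-2, 1))
            sim_size = float(10 ** rng.uniform(-2, 1))
            equipment.append(EquipmentItem(
                id=f"EQ-{i:03d}", description="generated unit",
                ref_cost=ref_cost, ref_year=year, stage_group=group,
                ref_size=ref_size, sim_size=sim_size,
                size_unit=str(rng.choice(["m3", "m2"])),
                lang_exponent=float(rng.uniform(0.2, 0.8))))
        else:
            equipment.append(EquipmentItem(
                id=f"EQ-{i:03d}", description="generated fixed-price unit",
                ref_cost=ref_cost, ref_year=year, stage_group=group))
    materials = []
    for i in range(n_materials):
        group = STAGE_GROUPS[rng.integers(len(STAGE_GROUPS))]
        materials.append(MaterialItem(
            name=f"MAT-{i:03d}",
            unit_price=float(10 ** rng.uniform(-1, 4)),
            price_unit="EUR/kg",
            annual_quantity=float(10 ** rng.uniform(1, 4)),
            quantity_unit="kg/year",
            stage_group=group))
    priors = [TriangularParam(name=f"{m.name} price",
                              target=("material", m.name),
                              baseline=m.unit_price,
                              low_conversion=-0.10, high_conversion=0.30)
              for m in materials]
    priors.append(TriangularParam(name="Discount rate",
                                  target=("finance", "discount_rate"),
                                  baseline=0.10, low_conversion=-0.40,
                                  high_conversion=0.40))
    priors.append(TriangularParam(name="Income tax rate",
                                  target=("finance", "tax_rate"),
                                  baseline=0.21, low_conversion=-0.40,
                                  high_conversion=0.40))
    return PlantScenario(
        name=f"generated-{seed}",
        equipment=equipment,
        materials=materials,
        priors=priors,
        mixing=MixingSpec(rotation_rate=float(rng.uniform(0.5, 6.0)),
                          impeller_diameter=0.12, vessel_diameter=0.23,
                          fluid_density=float(rng.uniform(500, 1200)),
                          fluid_viscosity=1e-3,
                          agitation_power=float(rng.uniform(10, 200)),
                          fluid_volume=0.008),
        monod=MonodParams(maintenance=float(rng.uniform(0.0, 0.1))),
        perfusion=PerfusionSpec(
            bleed_fraction=float(rng.uniform(0.05, 0.5)),
            recycle_condensation=float(rng.uniform(1.0, 3.0)),
            residence_time=float(rng.uniform(10.0, 40.0))),
        columns=_baseline_columns(),
        ivt_params=IVTParams(),
        shell=ShellSpec(),
    )


# ---------------------------------------------------------------------------
# full cost chain

def build_costs(scenario: PlantScenario,
                overrides: dict[tuple[str, str], float] | None = None
                ) -> tuple[CostBreakdown, FinanceParams]:
    """Run the scenario's cost chain; ``overrides`` perturbs material unit
    prices and finance rates (the Monte-Carlo hook)."""
    overrides = overrides or {}
    finance = scenario.finance
    fin_over = {key: v for (kind, key), v in overrides.items()
                if kind == "finance"}
    if fin_over:
        finance = dataclasses.replace(finance, **fin_over)
    materials = scenario.materials
    mat_over = {key: v for (kind, key), v in overrides.items()
                if kind == "material"}
    if mat_over:
        materials = [dataclasses.replace(m, unit_price=mat_over[m.name])
                     if m.name in mat_over else m for m in materials]
    index = scenario.cost_index_series
    by_group = equipment_group_costs(scenario.equipment, index,
                                     scenario.cost_year)
    delivered = sum(by_group.values())
    fci, tci = capital_from_equipment(delivered, scenario.capital_factors)
    c_r, _, mat_groups = bill_of_materials(materials)
    breakdown = CostBreakdown(
        delivered_equipment=delivered, FCI=fci, TCI=tci,
        C_L=finance.labor_cost,
        C_U=cleanroom_lcc(scenario.cleanroom, floor_at_zero=True)
        / finance.lifetime_years + finance.utilities_annual,
        C_W=0.0, C_R=c_r,
        equipment_by_group=by_group, materials_by_group=mat_groups)
    breakdown.COM_d = com_d(breakdown)
    return breakdown, finance


def make_mspd_rebuild(scenario: PlantScenario):
    """Closure ``rebuild(overrides) -> MSPD`` for the Monte-Carlo engine.

    Equipment costs are unaffected by the priors, so FCI/TCI are computed
    once; each call rebuilds only the bill of materials and finance rates.
    """
    index = scenario.cost_index_series
    delivered = sum(equipment_cost(e, index, scenario.cost_year)
                    for e in scenario.equipment)
    fci, tci = capital_from_equipment(delivered, scenario.capital_factors)
    base_fin = scenario.finance
    c_u = cleanroom_lcc(scenario.cleanroom, floor_at_zero=True) \
        / base_fin.lifetime_years + base_fin.utilities_annual
    names = [m.name for m in scenario.materials]
    quantities = np.array([m.annual_quantity for m in scenario.materials])
    base_prices = np.array([m.unit_price for m in scenario.materials])
    name_pos = {n: i for i, n in enumerate(names)}

    def rebuild(overrides: dict[tuple[str, str], float]) -> float:
        prices = base_prices.copy()
        fin = base_fin
        fin_over = {}
        for (kind, key), val in overrides.items():
            if kind == "material":
                prices[name_pos[key]] = val
            else:
                fin_over[key] = val
        if fin_over:
            fin = dataclasses.replace(fin, **fin_over)
        c_r = float(quantities @ prices)
        com = 0.18 * fci + 2.73 * fin.labor_cost + 1.23 * (c_u + c_r)
        return solve_mspd(com, fci, tci, fin)

    return rebuild
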