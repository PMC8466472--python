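"""Baseline plant fixture: the complete continuous mRNA-LNP scenario.

Transcribes the published equipment and raw-material tables of the
reference plant (8000 g API mRNA per year, ~270 million 30 ug doses),
the capital-investment factors, the triangular uncertainty priors, and the
process parameter blocks, so the whole chain is computable offline.

Only primary data are stored (reference costs/sizes/years, unit prices,
printed quantities); every derived column (scaled cost, escalated cost,
annual material cost) is recomputed by the costing module.
"""

from __future__ import annotations

from .costing import (CapitalFactors, CleanroomSpec, CostIndexSeries,
                      EquipmentItem, MaterialItem)
from .finance import FinanceParams, TriangularParam

# ---------------------------------------------------------------------------
# Equipment table: (id, description, ref_cost EUR, ref_year, stage_group,
#                   ref_size, sim_size, size_unit, lang_exponent)
# Fixed-price rows carry None sizes.

_EQUIPMENT_ROWS = [
    ("R-101", "Fermentation reactor", 34_013, 2013, "fermentation",
     0.065, 0.1, "m3", 0.6),
    ("R-102", "Perfusion reactor", 594_299, 2016, "fermentation",
     2.0, 1.0, "m3", 0.6),
    ("V-201", "Horizontal vessel", 12_450, 2013, "cell_lysis",
     2.5, 0.0005, "m3", 0.2),
    ("UF-201", "Ultrafiltration filter", 6_686, 2015, "cell_lysis",
     1.0, 0.023, "m2", 0.58),
    ("HIC-201", "Chromatography", 500_000, 2016, "cell_lysis",
     None, None, None, None),
    ("UF-202", "Ultrafiltration filter", 6_686, 2015, "cell_lysis",
     1.0, 0.0016, "m2", 0.58),
    ("AEX-201", "Chromatography", 500_000, 2016, "cell_lysis",
     None, None, None, None),
    ("UF-203", "Ultrafiltration filter", 6_686, 2015, "cell_lysis",
     1.0, 0.0016, "m2", 0.58),
    ("SEC-201", "Chromatography", 500_000, 2016, "cell_lysis",
     None, None, None, None),
    ("UF-204", "Ultrafiltration filter", 6_686, 2015, "cell_lysis",
     1.0, 0.0016, "m2", 0.58),
    ("C-301", "Container", 271, 2002, "linearization",
     0.21, 0.075, "m3", 0.2),
    ("P-301", "Pump", 500, 2021, "linearization", None, None, None, None),
    ("B-301", "Jacketed mixer", 29_931, 2020, "linearization",
     0.2, 0.075, "m3", 0.16),
    ("C-302", "Container", 271, 2002, "linearization",
     0.21, 0.075, "m3", 0.2),
    ("P-302", "Pump", 500, 2021, "linearization", None, None, None, None),
    ("UF-301", "Ultrafiltration filter", 6_686, 2015, "linearization",
     1.0, 0.0028, "m2", 0.58),
    ("AEX-301", "Chromatography", 500_000, 2016, "linearization",
     None, None, None, None),
    ("UF-302", "Ultrafiltration filter", 6_686, 2015, "linearization",
     1.0, 0.00047, "m2", 0.58),
    ("C-303", "Container", 271, 2002, "ivt", 0.21, 0.05, "m3", 0.2),
    ("P-303", "Pump", 500, 2021, "ivt", None, None, None, None),
    ("R-301", "Reactor", 74_699, 2002, "ivt", 0.4, 0.01, "m3", 0.5),
    ("R-302", "Reactor", 74_699, 2002, "ivt", 0.4, 0.01, "m3", 0.5),
    ("R-303", "Reactor", 74_699, 2002, "ivt", 0.4, 0.01, "m3", 0.5),
    ("C-304", "Container", 271, 2002, "ivt", 0.21, 0.05, "m3", 0.2),
    ("P-304", "Pump", 500, 2021, "ivt", None, None, None, None),
    ("UF-303", "Ultrafiltration filter", 6_686, 2015, "ivt",
     1.0, 0.006, "m2", 0.58),
    ("AFC-301", "Chromatography", 500_000, 2016, "ivt",
     None, None, None, None),
    ("UF-304", "Ultrafiltration filter", 6_686, 2015, "ivt",
     1.0, 0.005, "m2", 0.58),
    ("HPLC-301", "Chromatography", 500_000, 2016, "ivt",
     None, None, None, None),
    ("UF-305", "Ultrafiltration filter", 6_686, 2015, "ivt",
     1.0, 0.005, "m2", 0.58),
    ("B-401", "Non-jacketed mixer", 24_994, 2020, "formulation",
     0.2, 0.0025, "m3", 0.16),
    ("B-402", "Non-jacketed mixer", 24_994, 2020, "formulation",
     0.2, 0.0075, "m3", 0.16),
    ("P-401", "Pump", 500, 2021, "formulation", None, None, None, None),
    ("P-402", "Pump", 500, 2021, "formulation", None, None, None, None),
    ("uM-401", "Microfluidic mixer", 176_671, 2021, "formulation",
     None, None, None, None),
    ("TF-401", "Tangential flow filtration filter", 4_504, 2018,
     "formulation", 0.12, 3.0, "m2", 0.8),
    ("MS-401", "Molecular sieve", 1_800, 2021, "formulation",
     None, None, None, None),
]


def baseline_equipment() -> list[EquipmentItem]:
    return [EquipmentItem(id=r[0], description=r[1], ref_cost=float(r[2]),
                          ref_year=r[3], stage_group=r[4], ref_size=r[5],
                          sim_size=r[6], size_unit=r[7], lang_exponent=r[8])
            for r in _EQUIPMENT_ROWS]


# ---------------------------------------------------------------------------
# Raw materials: (name, unit_price, price_unit, annual_quantity,
#                 quantity_unit, stage_group, replacement_cycles)

_MATERIAL_ROWS = [
    ("Glucose", 0.24, "EUR/kg", 18_454, "kg/year", "fermentation", None),
    ("Diammonium phosphate", 0.83, "EUR/kg", 6_336, "kg/year",
     "fermentation", None),
    ("Ammonium sulfate", 0.124, "EUR/kg", 21_384, "kg/year",
     "cell_lysis", None),
    ("HIC resin", 2_064.0, "EUR/L", 2_206, "L/year", "cell_lysis", 100),
    ("AEX membrane", 989.0, "EUR/m2", 6, "m2/year", "cell_lysis", 100),
    ("HPLC resin", 10_892.0, "EUR/L", 1_476, "L/year", "ivt", 100),
    ("SEC resin", 10_892.0, "EUR/L", 2_546, "L/year", "cell_lysis", 150),
    ("Linearization restriction enzyme", 0.0051, "EUR/unit",
     22_464_000_000, "unit/year", "linearization", None),
    ("T7 RNA polymerase", 38.0, "EUR/mg", 39_000, "mg/year", "ivt", None),
    ("CleanCap Reagent (3' OMe) AG", 248.0, "EUR/mg", 216_000, "mg/year",
     "ivt", None),
    ("AFC resin", 10_892.0, "EUR/L", 51, "L/year", "ivt", 100),
    ("Ethanol", 6.8, "EUR/kg", 41_722, "kg/year", "formulation", None),
    ("Sodium citrate", 0.7, "EUR/kg", 102, "kg/year", "formulation", None),
    ("Dimethyldioctadecylammonium (DDAB)", 554.0, "EUR/g", 8_000, "g/year",
     "formulation", None),
    ("Cholesterol", 11.0, "EUR/g", 129_015, "g/year", "formulation", None),
    ("DMG-PEG2000", 166.0, "EUR/g", 228_584, "g/year", "formulation", None),
    ("DSPC", 172.0, "EUR/g", 65_996, "g/year", "formulation", None),
]


def baseline_materials() -> list[MaterialItem]:
    return [MaterialItem(name=r[0], unit_price=float(r[1]), price_unit=r[2],
                         annual_quantity=float(r[3]), quantity_unit=r[4],
                         stage_group=r[5], replacement_cycles=r[6])
            for r in _MATERIAL_ROWS]


# ---------------------------------------------------------------------------
# Cost index series.
#
# The table-consistent series encodes, per reference year, the escalation
# ratio implied by the equipment table's own reference-year and 2021-EUR
# columns (one anchor row per year); the published series holds the public
# CEPCI annual averages.  The table-consistent series is the default so the
# fixture reproduces its source table; both are available by name.

CEPCI_TABLE_CONSISTENT = CostIndexSeries(
    name="table_consistent",
    values={
        2002: 100.0 * 11_811 / 19_042,
        2013: 100.0 * 44_045 / 49_519,
        2015: 100.0 * 750 / 859,
        2016: 100.0 * 500_000 / 588_702,
        2018: 100.0 * 59_149 / 62_553,
        2020: 100.0 * 25_584 / 27_369,
        2021: 100.0,
    })

CEPCI_PUBLISHED = CostIndexSeries(
    name="published",
    values={2002: 395.6, 2013: 567.3, 2015: 556.8, 2016: 541.7,
            2018: 603.1, 2020: 596.2, 2021: 708.8})

COST_INDEX_SERIES = {s.name: s for s in (CEPCI_TABLE_CONSISTENT,
                                         CEPCI_PUBLISHED)}


# ---------------------------------------------------------------------------
# Uncertainty priors: material unit prices fluctuate -10 % / +30 %, the
# discount and income-tax rates +/-40 %, all triangular with the mode at
# the baseline.

_MATERIAL_PRIORS = [
    ("HIC resin price", "HIC resin", 2_064.0),
    ("AEX membrane price", "AEX membrane", 989.0),
    ("SEC resin price", "SEC resin", 10_892.0),
    ("Linearization restriction enzyme price",
     "Linearization restriction enzyme", 0.0051),
    ("T7 polymerase price", "T7 RNA polymerase", 38.0),
    ("CleanCap Reagent (3' OMe) AG price",
     "CleanCap Reagent (3' OMe) AG", 248.0),
    ("AFC resin price", "AFC resin", 10_892.0),
    ("HPLC resin price", "HPLC resin", 10_892.0),
    ("DDAB price", "Dimethyldioctadecylammonium (DDAB)", 554.0),
    ("Cholesterol price", "Cholesterol", 11.0),
    ("DMG-PEG2000 price", "DMG-PEG2000", 166.0),
    ("DSPC price", "DSPC", 172.0),
]


def baseline_priors() -> list[TriangularParam]:
    priors = [TriangularParam(name=n, target=("material", mat), baseline=b,
                              low_conversion=-0.10, high_conversion=0.30)
              for n, mat, b in _MATERIAL_PRIORS]
    priors.append(TriangularParam(
        name="Discount rate", target=("finance", "discount_rate"),
        baseline=0.10, low_conversion=-0.40, high_conversion=0.40))
    priors.append(TriangularParam(
        name="Income tax rate", target=("finance", "tax_rate"),
        baseline=0.21, low_conversion=-0.40, high_conversion=0.40))
    return priors


def baseline_capital_factors() -> CapitalFactors:
    return CapitalFactors()


def baseline_cleanroom() -> CleanroomSpec:
    return CleanroomSpec()


def baseline_finance() -> FinanceParams:
    return FinanceParams()
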