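"""End-to-end report runner: sizing -> costing -> finance (-> Monte-Carlo).

Produces a deterministic, JSON-serializable bundle with one section per
pipeline stage plus provenance (scenario hash, seed, package version) and a
warnings list (e.g. the agitation Froude criterion Fr < 0.1, SMB schedule
continuity).
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chromatography import (SMBSpec, check_schedule_continuity, kozeny_blake,
                             size_column, switch_time)
from .costing import group_shares
from .errors import MrnaPlantError
from .finance import monte_carlo_mspd, solve_mspd
from .ivt import mm_rate, initial_state, reactor_schedule, simulate_ivt
from .lnp import area_per_lipid, shell_counts
from .perfusion import froude, mixing_time, perfusion_steady_state, reynolds
from .scenario import PlantScenario, build_costs, make_mspd_rebuild

FROUDE_CRITERION = 0.1


@dataclass
class ReportBundle:
    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"sections": self.sections, "provenance": self.provenance,
                "warnings": self.warnings}

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_report(scenario: PlantScenario, seed: int = 0,
               monte_carlo_iterations: int = 0,
               out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the full chain on ``scenario``.

    Monte-Carlo runs only when ``monte_carlo_iterations`` > 0.  When
    ``out_dir`` is given the JSON report (and MC samples CSV) are written
    there.
    """
    bundle = ReportBundle()
    notes = bundle.warnings
    timings = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and isinstance(exc, MrnaPlantError):
                    raise MrnaPlantError(f"stage {name!r}: {exc}") from exc
        return _T()

    # -- upstream ----------------------------------------------------------
    with stage("upstream"):
        upstream = {}
        if scenario.mixing is not None:
            fr = froude(scenario.mixing)
            upstream["froude"] = fr
            upstream["reynolds_impeller"] = reynolds(scenario.mixing)
            upstream["reynolds_vessel"] = reynolds(scenario.mixing,
                                                   diameter="vessel")
            if scenario.mixing.agitation_power is not None:
                upstream["mixing_time_s"] = mixing_time(scenario.mixing)
            if fr >= FROUDE_CRITERION:
                notes.append(
                    f"upstream: Froude number {fr:.2f} violates the "
                    f"Fr < {FROUDE_CRITERION} uniform-mixing criterion")
        if scenario.monod is not None and scenario.perfusion is not None:
            ss = perfusion_steady_state(scenario.monod, scenario.perfusion)
            upstream["perfusion"] = dataclasses.asdict(ss)
        bundle.sections["upstream"] = _jsonable(upstream)

    # -- separations -------------------------------------------------------
    with stage("separations"):
        seps = {}
        for name, col in scenario.columns.items():
            entry = {}
            kb_ready = all(getattr(col, f) is not None for f in
                           ("linear_velocity", "bed_height",
                            "particle_diameter"))
            if kb_ready:
                entry["pressure_drop_bar"] = kozeny_blake(
                    col, solve_for="pressure_drop")
            if col.retention_time is not None:
                l_c, dia, packed = size_column(
                    scenario.process_flow_l_h, col.retention_time,
                    col.porosity, col.aspect_ratio)
                entry["sized_height_cm"] = l_c
                entry["sized_diameter_cm"] = dia
                entry["packed_volume_l"] = packed
                smb = SMBSpec(packed_volume=packed / 1000.0,
                              porosity=col.porosity,
                              tmb_volumetric_rate=scenario.process_flow_l_h
                              / 1000.0 / 60.0,
                              n_columns=col.n_columns)
                entry["switch_time_min"] = switch_time(smb)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    entry["schedule_continuous"] = check_schedule_continuity(
                        smb, col.retention_time)
                    notes.extend(f"separations[{name}]: {w.message}"
                                 for w in caught)
            seps[name] = entry
        bundle.sections["separations"] = _jsonable(seps)

    # -- ivt ---------------------------------------------------------------
    with stage("ivt"):
        ivt_sec = {}
        if scenario.ivt_params is not None:
            params = scenario.ivt_params
            ivt_sec["initial_rate_mM_nt_min"] = mm_rate(
                initial_state(params), params)
            traj = simulate_ivt(params, duration=240.0, step=1.0)
            final = traj[-1]
            ivt_sec["final_rna_mM_nt"] = final.RNA_nt
            ivt_sec["final_rna_transcript_mM"] = final.rna_transcripts(
                params.transcript_length)
            ivt_sec["final_limiting_ntp_mM"] = min(final.NTP_concs.values())
            sched = reactor_schedule(n_reactors=3, cycle_time=4.0,
                                     stagger_interval=80.0,
                                     occupancy_fraction=0.8)
            ivt_sec["schedule"] = {
                "n_reactors": sched.n_reactors,
                "cycle_time_h": sched.cycle_time,
                "stagger_min": sched.stagger_interval,
                "continuous_feed": sched.continuous_feed,
                "cycles_per_reactor_24h": [sched.cycles_completed(i)
                                           for i in range(sched.n_reactors)],
            }
        bundle.sections["ivt"] = _jsonable(ivt_sec)

    # -- lnp ---------------------------------------------------------------
    with stage("lnp"):
        lnp_sec = {}
        if scenario.shell is not None:
            counts = shell_counts(scenario.shell)
            lnp_sec["shell_counts"] = counts
            surface = sum(v for k, v in counts.items() if k != "CHOL")
            if surface > 0:
                lnp_sec["apl_nm2"] = area_per_lipid(
                    scenario.shell.particle_diameter, surface)
            lnp_sec["rna_copies"] = scenario.shell.rna_copies
        bundle.sections["lnp"] = _jsonable(lnp_sec)

    # -- costing -----------------------------------------------------------
    with stage("costing"):
        breakdown, finance = build_costs(scenario)
        eq_shares, eq_fracs = group_shares(breakdown.equipment_by_group)
        mat_shares, mat_fracs = group_shares(breakdown.materials_by_group)
        bundle.sections["costing"] = _jsonable({
            "delivered_equipment": breakdown.delivered_equipment,
            "FCI": breakdown.FCI,
            "TCI": breakdown.TCI,
            "C_L": breakdown.C_L,
            "C_U": breakdown.C_U,
            "C_R": breakdown.C_R,
            "COM_d": breakdown.COM_d,
            "equipment_by_group": breakdown.equipment_by_group,
            "materials_by_group": breakdown.materials_by_group,
            "equipment_shares_pct": eq_shares,
            "material_shares_pct": mat_shares,
        })

    # -- finance -----------------------------------------------------------
    with stage("finance"):
        mspd = solve_mspd(breakdown.COM_d, breakdown.FCI, breakdown.TCI,
                          finance)
        fin_sec = {"baseline_mspd_eur_per_dose": mspd,
                   "doses_per_year": finance.doses_per_year}
        mc = None
        if monte_carlo_iterations > 0:
            rebuild = make_mspd_rebuild(scenario)
            mc = monte_carlo_mspd(rebuild, scenario.priors,
                                  n=monte_carlo_iterations, seed=seed)
            fin_sec["monte_carlo"] = {
                "n_iterations": mc.n_iterations,
                "seed": mc.seed,
                "median": mc.median,
                "percentiles": mc.percentiles,
                "tornado": mc.tornado,
            }
        bundle.sections["finance"] = _jsonable(fin_sec)

    bundle.provenance = {
        "scenario": scenario.name,
        "scenario_hash": scenario.content_hash(),
        "seed": seed,
        "version": __version__,
        "timings_s": timings,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write_json(out / "report.json")
        if mc is not None:
            pd.DataFrame({"mspd_eur_per_dose": mc.samples}).to_csv(
                out / "mspd_samples.csv", index=False)
    return bundle
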