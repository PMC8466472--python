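"""Sizing of SMB chromatography trains and accumulation vessels.

The plasmid and mRNA purification steps run as simulated-moving-bed (SMB)
trains of four packed columns with periodically switched valve positions.
Sizing uses classical plate theory (Van Deemter, theoretical plate count),
the Kozeny-Blake pressure-drop relation for packed beds, and simple holdup
arithmetic for the accumulation/stabilisation vessels that buffer batches
into a continuous stream.

I/O follows the bench-unit vocabulary of the design tables (cm, cm/s, cP,
um, bar); conversion to SI happens internally, once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _units as u
from .errors import InvalidInputError, SingularFitError


@dataclass
class SMBSpec:
    """Simulated-moving-bed train: per-column packed volume V (m^3),
    porosity, equivalent true-moving-bed volumetric rate (m^3/min)."""

    packed_volume: float
    porosity: float
    tmb_volumetric_rate: float
    n_columns: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.porosity <= 1:
            raise InvalidInputError("porosity must be in (0, 1]")
        if self.n_columns < 2:
            raise InvalidInputError("n_columns must be >= 2")
        if self.packed_volume < 0:
            raise InvalidInputError("packed_volume must be >= 0")


@dataclass
class VanDeemterModel:
    """Plate height model H = A + B/v + C v (cm; v in cm/h).

    B (longitudinal diffusion) matters for gas chromatography and defaults
    to 0 for the liquid systems here.
    """

    A: float
    C: float
    B: float = 0.0

    def plate_height(self, v: float) -> float:
        if v <= 0:
            raise InvalidInputError("linear velocity must be > 0")
        return self.A + self.B / v + self.C * v


@dataclass
class ColumnSpec:
    """Packed-column parameters in bench units (see module docstring)."""

    pressure_drop: float | None = None   # bar
    linear_velocity: float | None = None  # cm/s
    bed_height: float | None = None      # cm
    kozeny_constant: float = 150.0
    viscosity: float = 1.0               # cP
    porosity: float = 0.3
    particle_diameter: float | None = None  # um
    n_columns: int = 4
    column_height: float | None = None   # cm
    column_diameter: float | None = None  # cm
    retention_time: float | None = None  # min
    aspect_ratio: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.porosity < 1:
            raise InvalidInputError("porosity must be in (0, 1) exclusive")
        if self.particle_diameter is not None and self.particle_diameter <= 0:
            raise InvalidInputError("particle_diameter must be > 0")
        if self.aspect_ratio <= 0:
            raise InvalidInputError("aspect_ratio must be > 0")


def switch_time(spec: SMBSpec) -> float:
    """SMB valve switch period t = V (1 - eps) / Vdot_s in minutes.

    This is the residence time of the equivalent true moving bed's solid
    phase inside one column.
    """
    if spec.tmb_volumetric_rate <= 0:
        raise InvalidInputError("tmb_volumetric_rate must be > 0")
    return spec.packed_volume * (1.0 - spec.porosity) / spec.tmb_volumetric_rate


def plate_count(t_r: float, w: float) -> float:
    """Theoretical plate count N = 16 (t_R / w)^2 (same time units)."""
    if w <= 0:
        raise InvalidInputError("peak width must be > 0")
    if t_r < 0:
        raise InvalidInputError("retention time must be >= 0")
    return 16.0 * (t_r / w) ** 2


def plate_height(model: VanDeemterModel, v: float) -> float:
    """Plate height H (cm) at mobile-phase linear velocity v (cm/h)."""
    return model.plate_height(v)


def fit_van_deemter(points: list[tuple[float, float]]) -> VanDeemterModel:
    """Ordinary least squares of H = A + C v on (v, H) pairs (B fixed 0)."""
    if len(points) < 2:
        raise InvalidInputError("need at least 2 (v, H) points")
    v = np.array([p[0] for p in points], dtype=float)
    h = np.array([p[1] for p in points], dtype=float)
    if np.ptp(v) == 0:
        if np.ptp(h) != 0:
            raise SingularFitError(
                "all velocities identical with differing plate heights: "
                "the A/C split is not identifiable")
        return VanDeemterModel(A=float(h[0]), C=0.0)
    X = np.column_stack([np.ones_like(v), v])
    (a, c), *_ = np.linalg.lstsq(X, h, rcond=None)
    return VanDeemterModel(A=float(a), C=float(c))


_KB_FIELDS = {"pressure_drop", "linear_velocity", "bed_height",
              "particle_diameter"}


def kozeny_blake(spec: ColumnSpec, solve_for: str = "pressure_drop") -> float:
    """Solve the Kozeny-Blake packed-bed relation for one unknown.

    dP = mu K0 (1 - eps)^2 L u / (d_p^2 eps^3), evaluated in SI and
    returned in the field's bench unit (bar, cm/s, cm or um).
    ``solve_for`` is one of pressure_drop / linear_velocity / bed_height /
    particle_diameter; all other fields must be set on ``spec``.
    """
    if solve_for not in _KB_FIELDS:
        raise InvalidInputError(f"solve_for must be one of {sorted(_KB_FIELDS)}")
    needed = _KB_FIELDS - {solve_for}
    for name in needed:
        if getattr(spec, name) is None:
            raise InvalidInputError(f"{name} must be set to solve for {solve_for}")
    if not 0 < spec.porosity < 1:
        raise InvalidInputError("porosity must be strictly inside (0, 1)")

    mu = u.cp_to_pas(spec.viscosity)
    k0 = spec.kozeny_constant
    eps = spec.porosity
    shape = k0 * (1.0 - eps) ** 2 / eps ** 3  # dimensionless

    def si(name):
        val = getattr(spec, name)
        return {"pressure_drop": u.bar_to_pa,
                "linear_velocity": lambda x: u.cm_to_m(x),  # per s
                "bed_height": u.cm_to_m,
                "particle_diameter": u.um_to_m}[name](val)

    if solve_for == "pressure_drop":
        dp = mu * shape * si("bed_height") * si("linear_velocity") \
            / si("particle_diameter") ** 2
        return u.pa_to_bar(dp)
    if solve_for == "linear_velocity":
        vel = si("pressure_drop") * si("particle_diameter") ** 2 \
            / (mu * shape * si("bed_height"))
        return u.m_to_cm(vel)
    if solve_for == "bed_height":
        length = si("pressure_drop") * si("particle_diameter") ** 2 \
            / (mu * shape * si("linear_velocity"))
        return u.m_to_cm(length)
    # particle_diameter
    dp2 = mu * shape * si("bed_height") * si("linear_velocity") \
        / si("pressure_drop")
    return math.sqrt(dp2) * 1e6  # m -> um


def size_column(volumetric_flow: float, retention_time: float,
                porosity: float = 0.3,
                aspect_ratio: float = 2.0) -> tuple[float, float, float]:
    """Cylindrical column dimensions from flow and retention time.

    The mobile-phase holdup is flow (L/h) x retention time (min); the packed
    volume is holdup / porosity; the cylinder satisfies L_c = aspect_ratio x D.
    Returns (L_c cm, D cm, packed volume L).
    """
    if volumetric_flow < 0 or retention_time < 0:
        raise InvalidInputError("flow and retention time must be >= 0")
    if not 0 < porosity <= 1:
        raise InvalidInputError("porosity must be in (0, 1]")
    if aspect_ratio <= 0:
        raise InvalidInputError("aspect_ratio must be > 0")
    holdup_l = volumetric_flow * retention_time / u.MIN_PER_H
    packed_l = holdup_l / porosity
    vol_cm3 = packed_l * 1000.0
    # V = pi D^2/4 * (AR * D)  =>  D = (4 V / (pi AR))^(1/3)
    diameter = (4.0 * vol_cm3 / (math.pi * aspect_ratio)) ** (1.0 / 3.0)
    return aspect_ratio * diameter, diameter, packed_l


def accumulation_vessel(inflow: float, cycle_duration: float) -> float:
    """Working volume (L) of a stabilisation vessel buffering one cycle:
    inflow (L/h) x cycle duration (h)."""
    if inflow < 0 or cycle_duration < 0:
        raise InvalidInputError("inflow and cycle_duration must be >= 0")
    return inflow * cycle_duration


def check_schedule_continuity(spec: SMBSpec,
                              retention_time_min: float) -> bool:
    """True when switch_time x n_columns >= retention time; otherwise the
    SMB cycle cannot keep a solute inside the train and a scheduling
    warning is emitted."""
    ok = switch_time(spec) * spec.n_columns >= retention_time_min
    if not ok:
        warnings.warn(
            "SMB schedule: switch_time x n_columns is shorter than the "
            "retention time; the train cannot sustain continuous elution",
            UserWarning, stacklevel=2)
    return ok
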