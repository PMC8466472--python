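"""In vitro transcription (IVT) reactor model.

T7 RNA polymerase elongates the transcript by consuming magnesium-complexed
nucleoside triphosphates (MgNTP^2-) and releasing one pyrophosphate (PPi)
per incorporated nucleotide; PPi then scavenges further Mg^2+ and
precipitates as Mg2P2O7, so the reaction slowly starves itself of both the
limiting NTP and free magnesium.  The rate law is a Michaelis-Menten form
in the *scarcest* MgNTP species and free Mg^2+:

    V = k_app [T7] [MgNTP][Mg] / ([MgNTP] + k1 [Mg] + k2)

with k_app = 2.04 min^-1, k1 = 0.23 (dimensionless on mM), k2 = 0.094 mM.
k1 is treated as dimensionless so the denominator is homogeneous in mM.

Magnesium speciation is closed in one of two ways.  The default is a 1:1
Mg-NTP binding equilibrium with a single dissociation constant
(``mg_ntp_kd``, default 0.1 mM, a typical MgNTP value): the bound pool B
solves B^2 - B(T + M + Kd) + T M = 0 for NTP total T and available Mg M,
and each base's MgNTP share is proportional to its NTP pool.  Setting
``mg_ntp_kd=None`` selects the stricter excess-Mg closure (all NTP
complexed, free Mg the remainder), which requires Mg to exceed total NTP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, StepSizeError
from .rsm import CodedRSM

BASES = ("A", "C", "G", "U")


@dataclass
class IVTParams:
    """Kinetic constants and feed composition of the IVT reaction."""

    k_app: float = 2.04                     # 1/min
    k1: float = 0.23                        # dimensionless multiplier on mM
    k2: float = 0.094                       # mM
    T7_conc: float = 0.5                    # uM
    NTP_concs: dict[str, float] = field(
        default_factory=lambda: {"A": 4.0, "C": 4.0, "G": 4.0, "U": 4.0})
    Mg_total: float = 10.0                  # mM
    transcript_length: int = 4000           # nt
    base_composition: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in BASES})
    ppi_mg_stoichiometry: float = 2.0       # Mg per precipitated PPi
    mg_ntp_kd: float | None = 0.1           # mM; None = excess-Mg closure

    def __post_init__(self) -> None:
        for name in ("k_app", "k1", "k2"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.T7_conc < 0 or self.Mg_total < 0:
            raise InvalidInputError("concentrations must be >= 0")
        if set(self.NTP_concs) != set(BASES):
            raise InvalidInputError(f"NTP_concs must cover bases {BASES}")
        if any(v < 0 for v in self.NTP_concs.values()):
            raise InvalidInputError("NTP concentrations must be >= 0")
        total = sum(self.base_composition.get(b, 0.0) for b in BASES)
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError("base_composition fractions must sum to 1")
        if self.transcript_length <= 0:
            raise InvalidInputError("transcript_length must be > 0")
        if self.mg_ntp_kd is not None and self.mg_ntp_kd <= 0:
            raise InvalidInputError("mg_ntp_kd must be > 0 or None")


@dataclass
class IVTState:
    """Reactor state at one time point (concentrations in mM).

    ``mgntp_concs`` holds the effective MgNTP^2- pools per base under the
    active speciation closure; when absent, the NTP pools are used directly
    (excess-Mg reading).
    """

    time: float                              # min
    NTP_concs: dict[str, float]
    Mg_free: float
    PPi: float                               # dissolved PPi (as MgP2O7^2-)
    Mg2P2O7_precipitate: float
    RNA_nt: float                            # mM nucleotide-equivalents
    mgntp_concs: dict[str, float] | None = None

    def rna_transcripts(self, transcript_length: int) -> float:
        """RNA in transcript-copy concentration units (mM of molecules)."""
        return self.RNA_nt / transcript_length


def _mg_partition(params: IVTParams, ntp_total: float,
                  precipitate: float, ppi_dissolved: float
                  ) -> tuple[float, float]:
    """(Mg bound to NTP, free Mg) under the configured closure."""
    available = params.Mg_total - ppi_dissolved \
        - params.ppi_mg_stoichiometry * precipitate
    if available <= 0:
        return 0.0, 0.0
    if ntp_total <= 0:
        return 0.0, available
    if params.mg_ntp_kd is None:
        if available < ntp_total - 1e-12:
            raise InvalidInputError(
                "available Mg below total NTP: the excess-Mg closure does "
                "not apply; supply mg_ntp_kd to use the binding equilibrium")
        return ntp_total, available - ntp_total
    s = ntp_total + available + params.mg_ntp_kd
    bound = 0.5 * (s - math.sqrt(s * s - 4.0 * ntp_total * available))
    bound = min(bound, ntp_total, available)
    return bound, available - bound


def _make_state(params: IVTParams, time: float, ntp: dict[str, float],
                precipitate: float, rna_nt: float) -> IVTState:
    ntp_total = sum(ntp.values())
    bound, free = _mg_partition(params, ntp_total, precipitate, 0.0)
    if ntp_total > 0:
        frac = bound / ntp_total
        mgntp = {b: v * frac for b, v in ntp.items()}
    else:
        mgntp = {b: 0.0 for b in BASES}
    return IVTState(time, dict(ntp), free, 0.0, precipitate, rna_nt, mgntp)


def initial_state(params: IVTParams) -> IVTState:
    return _make_state(params, 0.0, dict(params.NTP_concs), 0.0, 0.0)


def limiting_mgntp(state: IVTState) -> float:
    """The scarcest of the four effective MgNTP^2- concentrations (mM)."""
    pools = state.mgntp_concs if state.mgntp_concs is not None \
        else state.NTP_concs
    if set(pools) != set(BASES):
        raise InvalidInputError(f"state must carry all bases {BASES}")
    return min(pools.values())


def mm_rate(state: IVTState, params: IVTParams) -> float:
    """Transcription velocity (mM nucleotide / min) at the given state."""
    mgntp = limiting_mgntp(state)
    mg = state.Mg_free
    if mgntp < 0 or mg < -1e-12:
        raise InvalidInputError("concentrations must be non-negative")
    mg = max(mg, 0.0)
    t7_mm = params.T7_conc * 1e-3  # uM -> mM
    if mgntp == 0.0 or mg == 0.0 or t7_mm == 0.0:
        return 0.0
    denom = mgntp + params.k1 * mg + params.k2
    return params.k_app * t7_mm * mgntp * mg / denom


def simulate_ivt(params: IVTParams, duration: float,
                 step: float = 0.5) -> list[IVTState]:
    """Integrate the IVT bookkeeping over ``duration`` minutes.

    Explicit stepping with per-step adaptivity: a step that would overdraw
    the limiting NTP (or the Mg budget) is shortened so the pools empty
    smoothly.  Per incorporated nucleotide one NTP (apportioned by base
    composition) is consumed and one PPi released; released PPi
    precipitates with the configured Mg stoichiometry.  NTP/RNA, PPi and
    magnesium conservation are audited every step; a breach raises
    :class:`StepSizeError` advising a smaller step.
    """
    if step <= 0:
        raise InvalidInputError("step must be > 0")
    if duration < 0:
        raise InvalidInputError("duration must be >= 0")
    state = initial_state(params)
    traj = [state]
    frac = np.array([params.base_composition.get(b, 0.0) for b in BASES])
    stoich = params.ppi_mg_stoichiometry
    t = 0.0
    while t < duration - 1e-12:
        h = min(step, duration - t)
        rate = mm_rate(state, params)
        ntp_arr = np.array([state.NTP_concs[b] for b in BASES])
        h_eff = h
        if rate > 0:
            with np.errstate(divide="ignore"):
                exhaust = np.where(frac > 0, ntp_arr / (rate * frac), np.inf)
            h_eff = min(h_eff, float(exhaust.min()))
            if stoich > 0:
                mg_budget = params.Mg_total \
                    - stoich * state.Mg2P2O7_precipitate
                h_eff = min(h_eff, mg_budget / (stoich * rate))
        d_nt = rate * h_eff
        ntp_new = np.maximum(ntp_arr - d_nt * frac, 0.0)
        precipitate = state.Mg2P2O7_precipitate + d_nt
        rna = state.RNA_nt + d_nt
        new = _make_state(params, state.time + h_eff,
                          dict(zip(BASES, ntp_new.tolist())),
                          precipitate, rna)
        _audit_conservation(params, new)
        traj.append(new)
        state = new
        t += h_eff
        if rate == 0.0 and h_eff >= h:
            # reaction stalled; fast-forward without accumulating states
            if t < duration - 1e-12:
                state = _make_state(params, duration, dict(state.NTP_concs),
                                    state.Mg2P2O7_precipitate, state.RNA_nt)
                traj.append(state)
                break
    return traj


def _audit_conservation(params: IVTParams, state: IVTState,
                        tol: float = 1e-9) -> None:
    ntp0 = sum(params.NTP_concs.values())
    ntp_now = sum(state.NTP_concs.values()) + state.RNA_nt
    if abs(ntp_now - ntp0) > tol * max(ntp0, 1.0):
        raise StepSizeError(
            "phosphate/NTP conservation breached during integration; "
            "retry with a smaller step")
    ppi = state.PPi + state.Mg2P2O7_precipitate
    if abs(ppi - state.RNA_nt) > tol * max(ntp0, 1.0):
        raise StepSizeError("PPi bookkeeping breached; retry with a smaller step")
    # Mg: free + bound-to-NTP + precipitated must close to the total (or to
    # zero available Mg once the precipitate has consumed everything).
    bound, free = _mg_partition(params, sum(state.NTP_concs.values()),
                                state.Mg2P2O7_precipitate, state.PPi)
    accounted = free + bound + state.PPi \
        + params.ppi_mg_stoichiometry * state.Mg2P2O7_precipitate
    scale = max(params.Mg_total, 1.0)
    if accounted - params.Mg_total > tol * scale:
        raise StepSizeError(
            "magnesium conservation breached during integration; "
            "retry with a smaller step")
    if abs(free - state.Mg_free) > tol * scale:
        raise StepSizeError("magnesium partition inconsistent with state")


# ---------------------------------------------------------------------------
# design space and scheduling

def design_space_region(model: CodedRSM, response_floor: float,
                        resolution: int = 21) -> dict[str, tuple[float, float]]:
    """Admissible physical bounding box where the response >= floor.

    Grid-evaluates the response surface on a regular coded grid
    (``resolution`` points per factor) and returns, per factor, the
    physical (low, high) of the axis-aligned bounding box of admissible
    grid points.  An empty region returns ``{}``.
    """
    k = len(model.factor_names)
    axes = [np.linspace(-1.0, 1.0, resolution)] * k
    mesh = np.meshgrid(*axes, indexing="ij")
    coded = np.column_stack([m.ravel() for m in mesh])
    values = model.predict_coded(coded)
    mask = values >= response_floor
    if not mask.any():
        return {}
    admissible = coded[mask]
    phys = model.decode(admissible)
    return {f: (float(phys[:, i].min()), float(phys[:, i].max()))
            for i, f in enumerate(model.factor_names)}


@dataclass
class ReactorSchedule:
    """Staggered cyclic occupancy windows for a reactor train."""

    n_reactors: int
    cycle_time: float             # h
    stagger_interval: float       # min
    occupancy_fraction: float
    windows: list[list[tuple[float, float]]]   # per reactor, (start, end) h
    continuous_feed: bool

    def cycles_completed(self, reactor: int) -> int:
        return len(self.windows[reactor])


def reactor_schedule(n_reactors: int, cycle_time: float,
                     stagger_interval: float,
                     occupancy_fraction: float = 0.8,
                     horizon: float = 24.0) -> ReactorSchedule:
    """Build staggered cyclic windows over ``horizon`` hours.

    Reactor i starts at i x stagger and repeats every ``cycle_time``.
    Downstream feed is continuous iff several reactors interleave with
    stagger x n_reactors <= cycle time, i.e. some reactor is always
    discharging when a cycle completes; a single reactor (or a synchronous
    train) necessarily leaves gaps.
    """
    if n_reactors < 1:
        raise InvalidInputError("n_reactors must be >= 1")
    if cycle_time <= 0 or stagger_interval < 0:
        raise InvalidInputError("cycle_time > 0 and stagger >= 0 required")
    if not 0 < occupancy_fraction <= 1:
        raise InvalidInputError("occupancy_fraction must be in (0, 1]")
    stagger_h = stagger_interval / 60.0
    n_cycles = int(horizon // cycle_time)
    windows: list[list[tuple[float, float]]] = []
    for i in range(n_reactors):
        offset = i * stagger_h
        windows.append([(offset + k * cycle_time,
                         offset + (k + 1) * cycle_time)
                        for k in range(n_cycles)])
    continuous = n_reactors > 1 and stagger_interval > 0 \
        and stagger_h * n_reactors <= cycle_time + 1e-9
    return ReactorSchedule(n_reactors, cycle_time, stagger_interval,
                           occupancy_fraction, windows, continuous)
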