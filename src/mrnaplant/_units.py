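"""Unit conversions used at module boundaries.

All internal computation is SI; the bench/table-facing units (rpm, cP, bar,
micrometres, centimetres, litres) are converted exactly once, here.
"""

G_ACCEL = 9.81  # m/s^2

MIN_PER_H = 60.0
S_PER_MIN = 60.0
S_PER_H = 3600.0


def rpm_to_hz(rpm: float) -> float:
    return rpm / 60.0


def hz_to_rpm(hz: float) -> float:
    return hz * 60.0


def cp_to_pas(cp: float) -> float:
    """Centipoise to Pa*s."""
    return cp * 1e-3


def bar_to_pa(bar: float) -> float:
    return bar * 1e5


def pa_to_bar(pa: float) -> float:
    return pa * 1e-5


def cm_to_m(cm: float) -> float:
    return cm * 1e-2


def m_to_cm(m: float) -> float:
    return m * 1e2


def um_to_m(um: float) -> float:
    return um * 1e-6


def litre_to_m3(litre: float) -> float:
    return litre * 1e-3


def m3_to_litre(m3: float) -> float:
    return m3 * 1e3


def ml_per_min_to_l_per_h(ml_min: float) -> float:
    return ml_min * 60.0 / 1000.0


def angstrom2_to_nm2(a2: float) -> float:
    return a2 * 1e-2


def umol_to_mmol(um: float) -> float:
    """Micromolar to millimolar (per litre, so a plain 1e-3 factor)."""
    return um * 1e-3
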