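"""Unit conversions and physical constants.

All internal masses are grams, diameters nanometres, densities g/cm^3,
flow rates mL/min, dwell times milliseconds, concentrations ug/L.
Every conversion between those conventions lives here so that no module
carries its own silent factors.
"""

from __future__ import annotations

NM_PER_CM = 1.0e7

#: CIAAW standard atomic weights (conventional values).
ATOMIC_WEIGHT = {
    "H": 1.008,
    "O": 15.999,
    "Ti": 47.867,
    "Ag": 107.8682,
}


def molar_ratio_tio2_ti(rounded: bool = True) -> float:
    """Mass conversion factor MW(TiO2)/MW(Ti).

    The factor converts a detected Ti mass into the mass of the TiO2
    particle it came from.  ``rounded=True`` returns the conventional
    two-decimal value (1.67); ``rounded=False`` the full-precision ratio.
    """
    ratio = (ATOMIC_WEIGHT["Ti"] + 2.0 * ATOMIC_WEIGHT["O"]) / ATOMIC_WEIGHT["Ti"]
    return round(ratio, 2) if rounded else ratio


def nm_to_cm(d_nm: float) -> float:
    return d_nm / NM_PER_CM


def cm_to_nm(d_cm: float) -> float:
    return d_cm * NM_PER_CM


def ms_to_s(t_ms: float) -> float:
    return t_ms / 1000.0


def ml_per_min_to_l_per_s(v_ml_min: float) -> float:
    return v_ml_min * 1.0e-3 / 60.0


def ug_per_l_to_g_per_l(c_ug_l: float) -> float:
    return c_ug_l * 1.0e-6
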