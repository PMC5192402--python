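"""Unit conversions used throughout the package.

All internal computation is in SI (m, s, kg-free mass units via g/mol and
g/m^3).  Concentrations arrive as mg/L, which is numerically identical to
g/m^3, so mass-concentration "conversions" are identities kept explicit for
readability; molar conversions divide by the molar mass.
"""

from __future__ import annotations

import math

#: 1 L·m⁻²·h⁻¹ expressed in m·s⁻¹ (m³ water per m² membrane per second).
LMH_TO_M_PER_S = 1e-3 / 3600.0

#: seconds per hour
S_PER_H = 3600.0

#: 1 cm² in m²
CM2_TO_M2 = 1e-4

#: 1 mL in m³
ML_TO_M3 = 1e-6

#: 1 µm in m
UM_TO_M = 1e-6


def mg_per_L_to_g_per_m3(c: float) -> float:
    """mg/L → g/m³ (numerically the identity)."""
    return float(c)


def g_per_m3_to_mg_per_L(c: float) -> float:
    """g/m³ → mg/L (numerically the identity)."""
    return float(c)


def mg_per_L_to_mol_per_m3(c: float, molar_mass: float) -> float:
    """mg/L → mol/m³ given a molar mass in g/mol."""
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    return float(c) / float(molar_mass)


def mol_per_m3_to_mg_per_L(c: float, molar_mass: float) -> float:
    """mol/m³ → mg/L given a molar mass in g/mol."""
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    return float(c) * float(molar_mass)


def water_flux_to_m_per_s(jw_lmh: float) -> float:
    """Water flux L·m⁻²·h⁻¹ → m·s⁻¹."""
    return float(jw_lmh) * LMH_TO_M_PER_S


def mass_flux_to_ug_m2_h(j_g_m2_s: float) -> float:
    """Mass flux g·m⁻²·s⁻¹ → µg·m⁻²·h⁻¹."""
    return float(j_g_m2_s) * 1e6 * S_PER_H


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed
    experimental tables), unlike Python's banker's rounding."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
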