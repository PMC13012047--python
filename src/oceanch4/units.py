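"""Unit conventions and conversions.

Concentrations are stored as µmol m⁻³ throughout, which is numerically
identical to nmol L⁻¹ (nM).  All rate constants are y⁻¹.  Conversions to
mass units (Tg CH4 y⁻¹ for budgets) are centralized here.
"""

from __future__ import annotations

#: molar mass of CH4, g mol⁻¹
MOLAR_MASS_CH4 = 16.043

#: days per model year (Julian year, matches the y⁻¹ rate convention)
DAYS_PER_YEAR = 365.25

#: µmol m⁻³ is numerically identical to nM
UMOL_M3_PER_NM = 1.0


def umol_to_tg(umol: float) -> float:
    """Convert an amount of CH4 in µmol to Tg (1 Tg = 1e12 g)."""
    return umol * 1e-6 * MOLAR_MASS_CH4 / 1e12


def tg_to_umol(tg: float) -> float:
    """Convert Tg CH4 to µmol; inverse of :func:`umol_to_tg`."""
    return tg * 1e12 / MOLAR_MASS_CH4 * 1e6
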