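"""Unit system and the single internal→SI conversion layer.

Internal units throughout the package: length Å, time ps, charge e,
dipole e·Å, electric field mV/Å, volume Å³.  SI enters only inside the
dielectric conversion ``Re[ε]−1 = A/(ε₀·V·E₀)``, which this module
implements as a dimensionless ratio so that no caller ever mixes unit
systems by hand.
"""

from __future__ import annotations

import math

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12              # F/m (vacuum permittivity)
KB = 1.380649e-23                    # J/K
AMU = 1.66053906660e-27              # kg

# composite conversion factors
EA_TO_CM = ELEMENTARY_CHARGE * 1e-10   # e·Å  -> C·m
A3_TO_M3 = 1e-30                       # Å³   -> m³
MV_PER_A_TO_V_PER_M = 1e7              # mV/Å -> V/m
PS_TO_S = 1e-12

WATER_MASS_AMU = 18.0154  # O + 2 H, the TIP3P molecular mass


def susceptibility_ratio(amplitude_eA: float, volume_A3: float,
                         e0_mV_per_A: float) -> float:
    """Dimensionless ratio  M/(ε₀·V·E₀)  for a dipole amplitude.

    Parameters are in internal units (e·Å, Å³, mV/Å); the conversion to
    SI happens here and only here.  Applied to the in-phase amplitude A
    this gives ε′−1, applied to the quadrature amplitude B it gives ε″.
    """
    if volume_A3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_A3}")
    if e0_mV_per_A <= 0:
        raise ValueError(f"field amplitude must be positive, got {e0_mV_per_A}")
    num = amplitude_eA * EA_TO_CM
    den = EPS0 * volume_A3 * A3_TO_M3 * e0_mV_per_A * MV_PER_A_TO_V_PER_M
    return num / den


def amplitude_from_ratio(ratio: float, volume_A3: float,
                         e0_mV_per_A: float) -> float:
    """Inverse of :func:`susceptibility_ratio` (e·Å); round-trip identity."""
    den = EPS0 * volume_A3 * A3_TO_M3 * e0_mV_per_A * MV_PER_A_TO_V_PER_M
    return ratio * den / EA_TO_CM


def omega_rad_per_ps(freq_hz: float) -> float:
    """Angular frequency in rad/ps for a field frequency in Hz."""
    return 2.0 * math.pi * freq_hz * PS_TO_S


def density_kg_m3(mass_amu: float, volume_A3: float) -> float:
    """Mass density of `mass_amu` total mass in `volume_A3`."""
    return mass_amu * AMU / (volume_A3 * A3_TO_M3)
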