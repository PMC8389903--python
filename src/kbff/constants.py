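"""Physical constants and unit conversions.

The internal unit system is (nm, kJ/mol, ps, elementary charge e, K),
matching the conventions of molecular force-field tables.  SI conversions
happen only at I/O boundaries (e.g. conductivity in S/m, pressure in atm).
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1 (molar gas constant / 1000).
KB = 0.008_314_462_618

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.022_140_76e23

#: Elementary charge, C.
E_CHARGE = 1.602_176_634e-19

#: Coulomb constant e^2/(4 pi eps0), kJ mol^-1 nm e^-2.
KE = 138.935_458

#: Vacuum permittivity in internal units, e^2 mol kJ^-1 nm^-1.
EPS0 = 1.0 / (4.0 * np.pi * KE)

#: 1 atm expressed in internal pressure units, kJ mol^-1 nm^-3.
ATM = 101_325.0e-27 * N_AVOGADRO / 1000.0

#: 1 mol/L expressed as a number density, nm^-3.
MOLAR = N_AVOGADRO / 1.0e24


def thermal_energy(temperature: float) -> float:
    """k_B * T in kJ/mol.

    >>> round(thermal_energy(300.0), 3)
    2.494
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def concentration_to_density(molar: float) -> float:
    """Convert a concentration in mol/L to a number density in nm^-3."""
    return molar * MOLAR


def density_to_concentration(density: float) -> float:
    """Convert a number density in nm^-3 to a concentration in mol/L."""
    return density / MOLAR


def diffusion_to_si(d_nm2_ps: float) -> float:
    """Convert a diffusion constant from nm^2/ps to m^2/s."""
    return d_nm2_ps * 1.0e-6


def diffusion_from_si(d_m2_s: float) -> float:
    """Convert a diffusion constant from m^2/s to nm^2/ps."""
    return d_m2_s * 1.0e6
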