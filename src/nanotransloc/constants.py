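"""Physical constants and unit conversions.

Internal unit system for the electrohydrodynamic engine:
lengths in nm, energies in kBT, charges in e, times in s.  Electrostatic
potentials are dimensionless (thermal units kBT/e); surface charge
densities are magnitudes in e/nm^2.  Viscosity is kept in Pa*s and
pressure in Pa -- the combination P/eta has units 1/s, so streaming-flow
velocities come out directly in nm/s.
"""

import math

# CODATA 2018
E_CHARGE = 1.602176634e-19  # C
K_BOLTZMANN = 1.380649e-23  # J/K
EPSILON_0 = 8.8541878128e-12  # F/m
N_AVOGADRO = 6.02214076e23  # 1/mol

DEFAULT_TEMPERATURE = 298.15  # K (room temperature)
WATER_VISCOSITY = 8.91e-4  # Pa*s
WATER_PERMITTIVITY = 80.0  # relative
MEMBRANE_PERMITTIVITY = 2.0  # relative, lipid/protein membranes

ATM_TO_PA = 101325.0
MOLAR_TO_NM3 = N_AVOGADRO / 1.0e24  # 1 M = 0.602214076 nm^-3
NM_PER_ANGSTROM = 0.1


def thermal_energy(T: float = DEFAULT_TEMPERATURE) -> float:
    """kBT in joules."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return K_BOLTZMANN * T


def thermal_voltage(T: float = DEFAULT_TEMPERATURE) -> float:
    """kBT/e in volts (~25.7 mV at room temperature)."""
    return thermal_energy(T) / E_CHARGE


def volts_to_kT(V: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a voltage to thermal units (beta*e*V, dimensionless)."""
    return V / thermal_voltage(T)


def kT_to_volts(phi: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a dimensionless thermal-unit potential to volts."""
    return phi * thermal_voltage(T)


def pascal_to_kT_nm3(P: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a pressure in Pa to kBT/nm^3."""
    return P * 1.0e-27 / thermal_energy(T)


def molar_to_nm3(c: float) -> float:
    """Convert a molar concentration to a number density in nm^-3."""
    return c * MOLAR_TO_NM3


def nm3_to_molar(rho: float) -> float:
    """Convert a number density in nm^-3 to molar."""
    return rho / MOLAR_TO_NM3


def bjerrum_length(T: float = DEFAULT_TEMPERATURE,
                   eps_w: float = WATER_PERMITTIVITY) -> float:
    """Bjerrum length lB = beta e^2 / (4 pi eps0 eps_w), in nm.

    The distance at which two unit charges in the solvent interact with
    thermal energy kBT; ~0.7 nm in water at room temperature.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if eps_w <= 0:
        raise ValueError(f"permittivity must be positive, got {eps_w}")
    lb_m = E_CHARGE**2 / (4.0 * math.pi * EPSILON_0 * eps_w * thermal_energy(T))
    return lb_m * 1.0e9
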