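"""Physical constants and internal units.

Internal units throughout the package: length in Angstrom, time in
picoseconds, energy in kcal/mol, charge in elementary units, temperature
in Kelvin.  Forces are kcal/mol/A and diffusion coefficients A^2/ps.
"""

import math

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: Coulomb conversion factor, kcal*A/(mol*e^2): q_i q_j / r in these units
COULOMB = 332.0637

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: elementary charge, C
E_CHARGE = 1.602176634e-19

#: vacuum permittivity, C^2/(J*m)
EPS0 = 8.8541878128e-12

#: Boltzmann constant, J/K
KB_SI = 1.380649e-23

#: default solvent viscosity, Pa*s (water at 25 C)
WATER_VISCOSITY = 8.9e-4


def debye_length(ionic_strength_M: float, dielectric: float, temperature_K: float) -> float:
    """Debye screening length in Angstrom for a 1:1 electrolyte.

    lambda_D = sqrt(eps0 * eps_s * kB * T / (2 * NA * e^2 * I)), with the
    ionic strength converted from mol/L to mol/m^3.  At 0.15 M, 78.4 and
    298 K this evaluates to ~7.9 A.
    """
    if ionic_strength_M <= 0:
        return math.inf
    i_si = ionic_strength_M * 1000.0 * N_AVOGADRO  # ions/m^3
    lam_m = math.sqrt(EPS0 * dielectric * KB_SI * temperature_K / (2.0 * i_si * E_CHARGE**2))
    return lam_m * 1e10


def stokes_einstein_D(radius_A: float, temperature_K: float, viscosity_Pa_s: float = WATER_VISCOSITY) -> float:
    """Free-draining translational diffusion coefficient in A^2/ps."""
    d_si = KB_SI * temperature_K / (6.0 * math.pi * viscosity_Pa_s * radius_A * 1e-10)  # m^2/s
    return d_si * 1e20 / 1e12  # -> A^2/ps
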