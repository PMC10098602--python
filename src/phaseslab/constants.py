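"""Physical constants and unit conversions.

Internal unit system (LAMMPS-"real"-like):
    length  Angstrom (A)
    mass    g/mol (Da)
    energy  kcal/mol
    time    fs
    charge  elementary charges (e)
    temperature K
"""

from scipy import constants as _si

#: Boltzmann constant, kcal/mol/K
KB = _si.k * _si.N_A / (_si.calorie * 1000.0)

#: 1 Da*(A/fs)^2 in kcal/mol  (multiply 0.5*m*v^2 by this to get kinetic energy);
#: 1e-3 kg/mol * (1e-10 m / 1e-15 s)^2 = 1e7 J/mol
MV2E = 1e7 / (_si.calorie * 1000.0)

#: force-to-acceleration conversion: a [A/fs^2] = (F[kcal/mol/A] / m[Da]) * FTM2V
FTM2V = 1.0 / MV2E

#: Coulomb constant e^2*N_A/(4 pi eps0 * 1 A), in kcal/mol (times q_i q_j / (eps_r * r[A]))
COULOMB = (_si.e ** 2 * _si.N_A) / (4.0 * _si.pi * _si.epsilon_0 * 1e-10 * _si.calorie * 1000.0)

#: pressure conversion: 1 kcal/mol/A^3 in bar
PRESS2BAR = (_si.calorie * 1000.0 / _si.N_A) / 1e-30 / 1e5

#: mass-density conversion: 1 Da/A^3 in g/cm^3
DA_PER_A3_TO_G_CM3 = (1.0 / _si.N_A) / 1e-24


def debye_length_angstrom(ionic_strength_M: float, temperature_K: float,
                          epsilon_r: float) -> float:
    """Debye screening length in Angstrom for a monovalent electrolyte.

    lambda_D = sqrt(eps0 * eps_r * kB * T / (2 * N_A * e^2 * I)), I in mol/m^3.
    """
    if ionic_strength_M <= 0:
        raise ValueError("ionic strength must be positive")
    I = ionic_strength_M * 1000.0  # mol/m^3
    lam_m = (_si.epsilon_0 * epsilon_r * _si.k * temperature_K
             / (2.0 * _si.N_A * _si.e ** 2 * I)) ** 0.5
    return lam_m * 1e10
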