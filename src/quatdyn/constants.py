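"""Physical constants and unit conversions, centralized.

Package-wide unit conventions: coordinates in Å, times in ps, masses in
amu, energies in kJ/mol, entropies in kJ/(mol·K), temperatures in K.
All CODATA values come from :mod:`scipy.constants`.
"""

from __future__ import annotations

import math

from scipy import constants as _codata

#: Boltzmann constant, J/K.
KB = _codata.k

#: Reduced Planck constant, J·s.
HBAR = _codata.hbar

#: Molar gas constant, J/(mol·K).
R_GAS = _codata.R

#: Avogadro constant, 1/mol.
AVOGADRO = _codata.Avogadro

#: Atomic mass unit, kg.
AMU_KG = _codata.atomic_mass

#: Euler's number (the "e²" in the Schlitter bound is exp(1)², not charge).
EULER = math.e

#: Å expressed in metres.
ANGSTROM_M = 1e-10

#: Conversion factor amu·Å² → kg·m² (units of mass-weighted covariance).
AMU_A2_TO_KG_M2 = AMU_KG * ANGSTROM_M**2

#: Coulomb prefactor N_A·e²/(4πε₀), in kJ·mol⁻¹·nm·e⁻² (GROMACS convention).
#: Evaluates to ≈ 138.935458.
COULOMB_KJ_MOL_NM = (
    1e-3 * AVOGADRO * _codata.e**2 / (4.0 * math.pi * _codata.epsilon_0 * 1e-9)
)


def schlitter_scale(temperature: float) -> float:
    """Dimensionless scale k_B·T·e²/ħ² applied to covariance eigenvalues.

    The returned factor converts an eigenvalue of the mass-weighted
    covariance matrix expressed in amu·Å² into the dimensionless argument
    of the Schlitter determinant, ``ln det(1 + scale·σ)``.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature * EULER**2 / HBAR**2 * AMU_A2_TO_KG_M2
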