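"""Unit conventions and physical constants.

Internal conventions used throughout the package:

* lengths in nanometres,
* energies in units of k_B*T at the model reference temperature
  (310 K unless stated otherwise),
* masses in atomic mass units (g/mol),
* times in picoseconds,
* charges in units of the elementary charge e.

With (kJ/mol, nm, ps, amu) the usual molecular-simulation unit system is
consistent, so converting a force from kT/nm to kJ/mol/nm is a single
multiplication by ``kT_kjmol(T)``.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, kJ/(mol K)
KB_KJMOL = 0.008314462618

#: Coulomb constant e^2/(4 pi eps0) in kJ/mol * nm / e^2
KE_KJMOL_NM = 138.935458

#: Default model temperature (K)
T_DEFAULT = 310.0

#: Default relative permittivity of the implicit aqueous solvent
EPSILON_R_DEFAULT = 78.0

ANGSTROM_PER_NM = 10.0


def kT_kjmol(temperature: float = T_DEFAULT) -> float:
    """k_B*T in kJ/mol at the given temperature in kelvin."""
    return KB_KJMOL * temperature


def bjerrum_length(temperature: float = T_DEFAULT,
                   epsilon_r: float = EPSILON_R_DEFAULT) -> float:
    """Bjerrum length in nm: distance at which two unit charges interact
    with energy k_B*T in a medium of relative permittivity ``epsilon_r``."""
    return KE_KJMOL_NM / (epsilon_r * kT_kjmol(temperature))


def kjmol_to_kt(energy: float | np.ndarray, temperature: float = T_DEFAULT):
    return np.asarray(energy) / kT_kjmol(temperature)


def kt_to_kjmol(energy: float | np.ndarray, temperature: float = T_DEFAULT):
    return np.asarray(energy) * kT_kjmol(temperature)


def kt_to_kcalmol(energy: float | np.ndarray, temperature: float = T_DEFAULT):
    return np.asarray(energy) * kT_kjmol(temperature) / 4.184


def angstrom_to_nm(x):
    return np.asarray(x) / ANGSTROM_PER_NM


def nm_to_angstrom(x):
    return np.asarray(x) * ANGSTROM_PER_NM
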