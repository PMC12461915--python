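"""Physical constants and unit conversions.

Internal unit system follows the GROMACS convention: lengths in nm, times
in ps, energies in kJ/mol, charges in units of the elementary charge,
temperatures in K.  Observables that are conventionally quoted in other
units (viscosity in mPa·s, mass density in kg/m³, scattering lengths in
fm) carry explicit conversion factors defined here.
"""

from __future__ import annotations

# CODATA 2018
KB_J_PER_K = 1.380649e-23  # Boltzmann constant, J/K
KB_KJ_PER_MOL_K = 0.00831446261815324  # kJ/(mol K)
AVOGADRO = 6.02214076e23  # 1/mol
ATOMIC_MASS_KG = 1.66053906660e-27  # kg per dalton

# Length / time
NM_PER_M = 1e9
PS_PER_S = 1e12

#: 1 m²/s expressed in nm²/ps
M2_PER_S_TO_NM2_PER_PS = NM_PER_M**2 / PS_PER_S  # = 1e6

#: 1 Pa·s = 1000 mPa·s
PA_S_TO_MPA_S = 1e3

#: Ångström ↔ nm
A_PER_NM = 10.0


def kbt_kj_per_mol(temperature: float) -> float:
    """Thermal energy k_B·T in kJ/mol at the given temperature (K)."""
    return KB_KJ_PER_MOL_K * temperature
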