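"""Physical constants in the spectroscopic unit system used throughout.

All electronic-state energies, couplings and reorganization energies are
carried in wavenumbers (cm^-1); rates in s^-1; free energies of the
classical ensembles in kcal/mol; distances in angstroms; charges in units
of the elementary charge e.
"""

#: Boltzmann constant, cm^-1 K^-1.
K_B_CM = 0.6950348

#: Boltzmann constant, kcal mol^-1 K^-1 (for MD free-energy surfaces).
K_B_KCAL = 0.0019872041

#: Reduced Planck constant expressed as cm^-1 * s, i.e. hbar / (h c) * ...
#: chosen so that (2*pi/hbar) * V[cm^-1]^2 / sqrt(...) yields s^-1 directly.
HBAR_CM_S = 5.3088e-12

#: Coulomb interaction constant for point charges in e, distances in
#: angstrom and energies in cm^-1: e^2/(4 pi eps0) = 14.3996 eV*A, times
#: 8065.54 cm^-1/eV.
K_E_CM_ANG = 116140.0

#: Default simulation temperature, kelvin.
T_DEFAULT = 300.0

#: Thermal energy at a given temperature, cm^-1.
def kbt_cm(temperature: float = T_DEFAULT) -> float:
    return K_B_CM * temperature


def kbt_kcal(temperature: float = T_DEFAULT) -> float:
    """Thermal energy at ``temperature``, kcal/mol."""
    return K_B_KCAL * temperature
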