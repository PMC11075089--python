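"""Physical constants and conventions used throughout the package.

Units follow the molecular-simulation convention: lengths in Å, energies in
kcal/mol, charges in units of the elementary charge e, concentrations in
mol/L, particle densities in Å^-3.
"""

#: Molar gas constant, kcal/(mol·K).
GAS_CONSTANT_R = 1.9872e-3

#: Default simulation/analysis temperature, K.
DEFAULT_TEMPERATURE = 298.16

#: Coulomb constant, kcal·Å/(mol·e^2); vacuum, no dielectric screening.
COULOMB_KCAL = 332.0637

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Conversion factor: (mol/L) -> particles per Å^3.
#: 1 L = 1e27 Å^3, so n [Å^-3] = c [mol/L] * N_A / 1e27.
MOLAR_TO_PER_A3 = AVOGADRO / 1.0e27

#: TIP3P water partial charges, e.
TIP3P_CHARGES = {"O": -0.834, "H": 0.417}
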