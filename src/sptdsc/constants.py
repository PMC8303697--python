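"""Physical constants shared across the package.

All packing calculations run in Angstrom-based units (number densities in
molecules/A^3); energies are reported in kJ/mol.
"""

#: Gas constant, J K^-1 mol^-1.
R = 8.31446

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214e23

#: mol/L -> molecules/A^3 (N_A / 1e27; 1 L = 1e27 A^3).
MOLAR_TO_PER_A3 = N_AVOGADRO / 1e27

#: Molar mass of water, g/mol (anhydrous-registry convention).
M_WATER = 18.015

#: 0 degrees Celsius in kelvin.
T_CELSIUS_OFFSET = 273.15

#: Reference temperature for the solution-state analyses, K (25 C).
T_REF = 298.15

#: Standard pressure, Pa (used only by the optional pressure-volume term).
P_STANDARD = 101325.0
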